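"""Configurable Charlson comorbidity index map (code → category → weight).

The bundled default map is *synthetic*: its 17 categories carry the classic
Charlson weights, but the concept codes are synthetic tokens matching the
bundled claims generator's condition vocabulary, not any real coding system.
Real-vocabulary maps are user-supplied via :func:`load_charlson_map`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class CharlsonMap:
    """Maps condition concept codes to comorbidity categories with weights.

    The index score for a covariate window is the sum of weights over the
    *distinct* categories observed in the window (repeat codes and multiple
    codes within one category count once).
    """

    code_to_category: dict[str, str]
    category_weight: dict[str, int]

    def score(self, codes) -> int:
        cats = {self.code_to_category[c] for c in codes if c in self.code_to_category}
        return sum(self.category_weight[c] for c in cats)


def _from_frame(df: pd.DataFrame) -> CharlsonMap:
    required = {"concept_code", "category", "weight"}
    if missing := required - set(df.columns):
        raise ValueError(f"charlson map missing columns: {sorted(missing)}")
    if (df["weight"] < 0).any():
        raise ValueError("charlson weights must be >= 0")
    conflicting = df.groupby("category")["weight"].nunique()
    if (conflicting > 1).any():
        bad = conflicting[conflicting > 1].index.tolist()
        raise ValueError(f"conflicting weights for categories: {bad}")
    return CharlsonMap(
        code_to_category=dict(zip(df["concept_code"], df["category"])),
        category_weight=dict(
            zip(df["category"], df["weight"].astype(int))
        ),
    )


def load_charlson_map(path: str | Path) -> CharlsonMap:
    """Load a user-supplied code→category→weight CSV."""
    return _from_frame(pd.read_csv(path, dtype={"concept_code": str}))


def default_charlson_map() -> CharlsonMap:
    """The bundled synthetic-token 17-category map."""
    with resources.files("momlink.data").joinpath(
        "charlson_synthetic.csv"
    ).open("r") as fh:
        return _from_frame(pd.read_csv(fh, dtype={"concept_code": str}))
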