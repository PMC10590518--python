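"""Static HTML characterization report: SMD table plus prevalence scatter.

A self-contained single-file replacement for an interactive results viewer:
the covariate-balance table (sorted by |SMD|) and the linked-vs-non-linked
prevalence scatter, with the figure inlined as SVG.
"""

from __future__ import annotations

import html
import io
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .characterization import CohortComparison, SMD_THRESHOLD


def _scatter_svg(comparison: CohortComparison) -> str:
    fig, ax = plt.subplots(figsize=(5, 5))
    s = comparison.scatter
    if len(s):
        ax.scatter(s["prev_linked"], s["prev_nonlinked"], s=12, alpha=0.6)
    lim = 1.0
    if len(s):
        lim = max(0.05, float(s[["prev_linked", "prev_nonlinked"]].max().max()) * 1.1)
    ax.plot([0, lim], [0, lim], color="grey", lw=1, ls="--")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("prevalence, linked cohort")
    ax.set_ylabel("prevalence, non-linked cohort")
    ax.set_title("Covariate prevalence: linked vs non-linked")
    buf = io.StringIO()
    fig.savefig(buf, format="svg", bbox_inches="tight")
    plt.close(fig)
    return buf.getvalue()


def write_html_report(
    comparison: CohortComparison,
    path: str | Path,
    title: str = "Linked vs non-linked characterization",
    max_rows: int = 200,
) -> Path:
    """Write a static single-file HTML report for one cohort comparison."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    comp = comparison.comparisons
    n_flagged = int(comp["flag_meaningful"].sum())
    pct_balanced = (
        100.0 * float((comp["smd"].abs() <= SMD_THRESHOLD).mean())
        if len(comp) else float("nan")
    )
    table = comp.head(max_rows).to_html(
        index=False, float_format=lambda v: f"{v:.4g}", border=0
    )
    body = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{html.escape(title)}</title>
<style>
 body {{ font-family: sans-serif; margin: 2em; }}
 table {{ border-collapse: collapse; font-size: 13px; }}
 th, td {{ padding: 3px 8px; border-bottom: 1px solid #ddd; text-align: right; }}
 th:first-child, td:first-child {{ text-align: left; }}
</style></head><body>
<h1>{html.escape(title)}</h1>
<p>{len(comp)} covariates compared; {n_flagged} with |SMD| &gt; {SMD_THRESHOLD}
({pct_balanced:.1f}% balanced). SMD sign: (non-linked − linked) / pooled SD.</p>
{_scatter_svg(comparison)}
<h2>Covariates sorted by |SMD|</h2>
{table}
</body></html>
"""
    path.write_text(body)
    return path
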