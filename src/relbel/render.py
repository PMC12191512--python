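"""Report rendering: CSV and aligned-text tables.

Display precision mirrors the conventions of published evidence tables
— three decimals for weights, two for probability contents, one for
interval endpoints — while JSON sidecars keep full precision.  An empty
plausible region renders as the empty-set symbol.
"""

from __future__ import annotations

import io

import numpy as np

__all__ = ["format_region", "row_from_report", "rows_to_csv", "rows_to_text"]

EMPTY = "∅"


def _fmt_weight(w) -> str:
    return f"{float(w):.3f}"


def _fmt_content(c) -> str:
    return f"{float(c):.2f}"


def format_region(region) -> str:
    """Render a plausible region: intervals to 1 dp, point sets verbatim."""
    if region is None or len(region) == 0:
        return EMPTY
    parts = []
    for item in region:
        if isinstance(item, tuple) and len(item) == 2 and all(
            isinstance(v, (int, float, np.floating)) for v in item
        ):
            parts.append(f"({item[0]:.1f},{item[1]:.1f})")
        else:
            parts.append(str(item))
    if all(not p.startswith("(") for p in parts):
        return "{" + ",".join(parts) + "}"
    return " U ".join(parts)


def _fmt_estimate(est) -> str:
    if est is None:
        return "-"
    if isinstance(est, (int, float, np.floating)):
        return f"{float(est):.1f}"
    return str(est)


def row_from_report(label: str, report, weight=None) -> dict:
    """Flatten an EvidenceReport into a display row."""
    row = {
        "label": label,
        "estimate": _fmt_estimate(report.estimate),
        "plausible_region": format_region(report.plausible_region),
        "posterior_content": _fmt_content(report.posterior_content),
        "prior_content": _fmt_content(report.prior_content),
    }
    if weight is not None:
        row["weight"] = _fmt_weight(weight)
    return row


def rows_to_csv(rows) -> str:
    """Serialize display rows (list of dicts) to CSV text."""
    if not rows:
        return ""
    cols: list = []
    for r in rows:
        for k in r:
            if k not in cols:
                cols.append(k)
    buf = io.StringIO()
    buf.write(",".join(cols) + "\n")
    for r in rows:
        buf.write(",".join(f'"{r.get(c, "")}"' if "," in str(r.get(c, ""))
                           else str(r.get(c, "")) for c in cols) + "\n")
    return buf.getvalue()


def rows_to_text(rows) -> str:
    """Aligned fixed-width text rendering of display rows."""
    if not rows:
        return ""
    cols: list = []
    for r in rows:
        for k in r:
            if k not in cols:
                cols.append(k)
    widths = {
        c: max(len(c), *(len(str(r.get(c, ""))) for r in rows)) for c in cols
    }
    lines = ["  ".join(c.ljust(widths[c]) for c in cols)]
    for r in rows:
        lines.append("  ".join(str(r.get(c, "")).ljust(widths[c]) for c in cols))
    return "\n".join(lines) + "\n"
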