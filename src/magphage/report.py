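"""Human-readable and machine-readable run reporting."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import pandas as pd


def format_percent(numerator: int, denominator: int, decimals: int = 0) -> str:
    """Format a count ratio as a percentage string.

    Rounds half away from zero at the requested precision (so 23.379% at
    0 decimals prints ``23%`` and 72.885% at 1 decimal prints ``72.9%``).
    A zero denominator yields ``"NA"``.
    """
    if denominator == 0:
        return "NA"
    value = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    rounded = value.quantize(quantum, rounding=ROUND_HALF_UP)
    return f"{rounded}%"


def summarize_mag_quality(metadata: pd.DataFrame) -> dict[str, int]:
    """Count medium- and high-quality MAGs in a metadata table.

    Admitted MAGs have completeness >= 70% and contamination <= 5%;
    medium quality is completeness in [70, 90], high quality is above
    90%.  Returns ``{"medium": ..., "high": ..., "total": ...}``.
    """
    comp = metadata["completeness"].astype(float)
    admitted = (comp >= 70) & (metadata["contamination"].astype(float) <= 5)
    high = int((admitted & (comp > 90)).sum())
    medium = int((admitted & (comp <= 90)).sum())
    return {"medium": medium, "high": high, "total": medium + high}


def render_report(report: dict) -> str:
    """Render the machine-readable report dict as a plain-text summary.

    Thousands separators appear here only, never in TSV outputs.  The
    body is a pure function of the report dict, so identical runs render
    byte-identical text.
    """
    lines = ["MAG prophage census report", "=" * 26, ""]

    def fmt(value):
        if isinstance(value, bool):
            return str(value)
        if isinstance(value, int):
            return f"{value:,}"
        if isinstance(value, float):
            return f"{value:.4g}"
        return str(value)

    def emit(d: dict, indent: int = 0) -> None:
        for key, value in d.items():
            if isinstance(value, dict):
                lines.append(" " * indent + f"{key}:")
                emit(value, indent + 2)
            elif isinstance(value, list):
                lines.append(" " * indent + f"{key}: " + ", ".join(fmt(v) for v in value))
            else:
                lines.append(" " * indent + f"{key}: {fmt(value)}")

    emit(report)
    lines.append("")
    return "\n".join(lines)
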