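"""Summary arithmetic and cross-module reporting.

Small, deliberately explicit helpers for the bookkeeping a study summary
reports: combining the known/novel halves of a consensus prediction set,
expressing one regulator's target count as a percentage share of a
total, and aggregating per-module results into a JSON/Markdown summary.
"""

from __future__ import annotations

import json
from pathlib import Path


def combined_total(known: int, novel: int) -> int:
    """Total of a split count (e.g. known + novel consensus targets)."""
    if known < 0 or novel < 0:
        raise ValueError("counts must be non-negative")
    return known + novel


def percent_share(part: int, total: int, digits: int = 2) -> float:
    """Share of a total as a percentage, rounded to ``digits`` places."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * part / total, digits)


def summarize(sections: dict[str, dict]) -> dict:
    """Assemble a nested pipeline summary from per-module dictionaries."""
    return {name: dict(content) for name, content in sections.items()}


def write_summary(summary: dict, outdir: str | Path) -> None:
    """Write the summary as JSON and a small Markdown digest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    lines = ["# Pipeline summary", ""]
    for section, content in summary.items():
        lines.append(f"## {section}")
        for key, value in content.items():
            lines.append(f"- {key}: {value}")
        lines.append("")
    (out / "summary.md").write_text("\n".join(lines))
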