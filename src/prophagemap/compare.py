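"""Comparison of mapped prophage regions with bioinformatic predictions.

Prophage-prediction tools (PHASTER, PhiSpy, Prophinder and kin) emit
intervals that are often fragmented, truncated, or spurious relative to the
prophage delineated by induced-phage read mapping.  This module ingests
their interval output (BED or GFF3), matches each prediction to the mapped
core region with the greatest base overlap, and quantifies agreement:
Jaccard index, base-level precision/recall of the prediction against the
mapped core, and signed boundary offsets.  Matching is many-to-one by
design — several fragmented predictions may hit one core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["PredictionInterval", "OverlapReport", "load_intervals", "compare_intervals"]


@dataclass(frozen=True)
class PredictionInterval:
    """One predicted prophage interval, 0-based half-open."""

    replicon_id: str
    start: int
    end: int
    tool: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def load_intervals(path, format: str = "BED", tool: str | None = None) -> list[PredictionInterval]:
    """Load prediction intervals from BED or GFF3, normalized to 0-based half-open.

    BED coordinates pass through; GFF3 start is decremented.  The tool name
    comes from the GFF3 source column unless ``tool`` is given; BED input
    requires ``tool``.  Malformed lines are rejected with their line number.
    """
    fmt = format.upper()
    if fmt not in ("BED", "GFF3"):
        raise ValueError(f"format must be BED or GFF3, got {format!r}")
    out: list[PredictionInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                if fmt == "BED":
                    if len(parts) < 3:
                        raise ValueError("fewer than 3 BED columns")
                    rid, s, e = parts[0], int(parts[1]), int(parts[2])
                    label = parts[3] if len(parts) > 3 else ""
                    t = tool or "unknown"
                else:
                    if len(parts) < 5:
                        raise ValueError("fewer than 5 GFF3 columns")
                    rid, source = parts[0], parts[1]
                    s, e = int(parts[3]) - 1, int(parts[4])
                    label = parts[2]
                    t = tool or source
                if e <= s:
                    raise ValueError(f"end {e} <= start {s} after normalization")
                out.append(PredictionInterval(rid, s, e, t, label))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
    return out


@dataclass(frozen=True)
class Match:
    prediction: PredictionInterval
    core_start: int
    core_end: int
    jaccard: float
    precision: float
    recall: float
    left_offset: int
    right_offset: int


@dataclass
class OverlapReport:
    """Per-prediction match metrics plus per-tool unmatched counts."""

    matches: list[Match]
    unmatched: dict[str, int] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "tool": m.prediction.tool,
                "label": m.prediction.label,
                "replicon": m.prediction.replicon_id,
                "pred_start": m.prediction.start + 1,
                "pred_end": m.prediction.end,
                "core_start": m.core_start + 1,
                "core_end": m.core_end,
                "jaccard": m.jaccard,
                "precision": m.precision,
                "recall": m.recall,
                "left_offset": m.left_offset,
                "right_offset": m.right_offset,
            }
            for m in self.matches
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "tool", "label", "replicon", "pred_start", "pred_end",
                "core_start", "core_end", "jaccard", "precision", "recall",
                "left_offset", "right_offset",
            ],
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_json(self, path=None):
        doc = {
            "matches": self.to_dataframe().to_dict(orient="records"),
            "unmatched_per_tool": self.unmatched,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(doc, fh, indent=2)
        return doc


def _intersection(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def compare_intervals(called, predictions) -> OverlapReport:
    """Match each prediction to the called core with the greatest overlap.

    ``called`` may be a :class:`~prophagemap.delineate.DelineationResult` or
    any iterable of regions with ``replicon_id``/``start``/``end``/``klass``
    (only ``klass == "core"`` regions participate; objects without ``klass``
    are all treated as cores).  Ties break by smaller summed absolute
    boundary offset, then by leftmost core.  Predictions overlapping no core
    are counted per tool.
    """
    regions = getattr(called, "regions", called)
    cores = [
        r for r in regions if getattr(r, "klass", "core") == "core"
    ]
    matches: list[Match] = []
    unmatched: dict[str, int] = {}
    for pred in predictions:
        best = None
        for c in cores:
            if c.replicon_id != pred.replicon_id:
                continue
            inter = _intersection((pred.start, pred.end), (c.start, c.end))
            if inter == 0:
                continue
            lo = pred.start - c.start
            ro = pred.end - c.end
            key = (-inter, abs(lo) + abs(ro), c.start)
            if best is None or key < best[0]:
                best = (key, c, inter, lo, ro)
        if best is None:
            unmatched[pred.tool] = unmatched.get(pred.tool, 0) + 1
            continue
        _, core, inter, lo, ro = best
        union = pred.length + (core.end - core.start) - inter
        matches.append(
            Match(
                prediction=pred,
                core_start=core.start,
                core_end=core.end,
                jaccard=inter / union,
                precision=inter / pred.length,
                recall=inter / (core.end - core.start),
                left_offset=lo,
                right_offset=ro,
            )
        )
    for pred in predictions:
        unmatched.setdefault(pred.tool, 0)
    return OverlapReport(matches, unmatched)
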