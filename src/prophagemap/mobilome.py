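"""Insertion-sequence (IS) mobilome profiling from annotation intervals.

Consumes externally produced IS annotations (ISEscan-style TSV or BED) and
computes the descriptive statistics that characterize a genome's IS load:
totals and densities per replicon and per genome, windowed density tracks,
log-normalized per-family abundances grouped by transposase catalytic class
(DDE / DEDD / HUH / unclassified), consecutive same-family duplicates, and
a token screen of gene annotations for plasmid backbone operons (repABC,
tra, par).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ISAnnotation",
    "MobilomeSummary",
    "FAMILY_CLASS",
    "family_class",
    "load_is_bed",
    "is_totals_and_density",
    "windowed_density",
    "family_abundance",
    "consecutive_duplicates",
    "plasmid_feature_screen",
]

# Transposase catalytic classes by IS family.  DEDD is the single family
# IS110; HUH is the single family IS91; ISCNY is not yet classified; every
# other family carries a DDE-type transposase.
FAMILY_CLASS = {"IS110": "DEDD", "IS91": "HUH", "ISCNY": "NA"}


def family_class(family: str) -> str:
    return FAMILY_CLASS.get(family, "DDE")


@dataclass(frozen=True)
class ISAnnotation:
    """One annotated IS copy, 0-based half-open."""

    replicon_id: str
    start: int
    end: int
    family: str
    type_class: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        expected = family_class(self.family)
        if self.type_class == "":
            object.__setattr__(self, "type_class", expected)
        elif self.type_class != expected:
            raise ValueError(
                f"family {self.family!r} is class {expected}, got {self.type_class!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def load_is_bed(path) -> list[ISAnnotation]:
    """Load IS annotations from BED (family in the name column)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: need >= 4 BED columns (family in name)")
            try:
                out.append(ISAnnotation(parts[0], int(parts[1]), int(parts[2]), parts[3]))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
    return out


@dataclass
class MobilomeSummary:
    """Per-replicon and genome-level IS totals and densities."""

    per_replicon: pd.DataFrame  # replicon, is_count, length_bp, density_per_mb
    genome_count: int
    genome_length: int
    genome_density_per_mb: float
    rounding: str = "none"
    metadata: dict = field(default_factory=dict)

    def reported_density(self, density: float) -> float | int:
        return round(density) if self.rounding == "nearest" else density


def is_totals_and_density(
    annotations,
    replicon_lengths: dict[str, int],
    rounding: str = "none",
) -> MobilomeSummary:
    """IS counts and densities (no./Mb) per replicon and for the whole genome.

    Density is count / (length / 1e6); rounding ("none" or "nearest") is a
    reporting convention only and is recorded in the summary metadata.
    """
    if rounding not in ("none", "nearest"):
        raise ValueError("rounding must be 'none' or 'nearest'")
    counts: dict[str, int] = {rid: 0 for rid in replicon_lengths}
    for a in annotations:
        if a.replicon_id not in replicon_lengths:
            raise ValueError(f"annotation on unknown replicon {a.replicon_id!r}")
        counts[a.replicon_id] += 1
    rows = []
    for rid, n in replicon_lengths.items():
        dens = counts[rid] / (n / 1e6)
        rows.append(
            {
                "replicon": rid,
                "is_count": counts[rid],
                "length_bp": n,
                "density_per_mb": round(dens) if rounding == "nearest" else dens,
            }
        )
    total_count = sum(counts.values())
    total_len = sum(replicon_lengths.values())
    gdens = total_count / (total_len / 1e6)
    return MobilomeSummary(
        per_replicon=pd.DataFrame(rows),
        genome_count=total_count,
        genome_length=total_len,
        genome_density_per_mb=round(gdens) if rounding == "nearest" else gdens,
        rounding=rounding,
        metadata={"density_definition": "count / (length_bp / 1e6)", "rounding": rounding},
    )


def windowed_density(
    annotations,
    replicon_length: int,
    window: int,
    normalize: bool = False,
) -> np.ndarray:
    """Per-window IS counts by the midpoint rule (an IS is counted once).

    With ``normalize=True`` the track is scaled as a proportion of its
    maximum, so the maximum is 1.0 whenever any IS exists.
    """
    if window < 100:
        raise ValueError("window must be >= 100 bp")
    n_windows = int(np.ceil(replicon_length / window))
    counts = np.zeros(n_windows)
    for a in annotations:
        w = int(a.midpoint // window)
        if 0 <= w < n_windows:
            counts[w] += 1
    if normalize and counts.max() > 0:
        counts = counts / counts.max()
    return counts


def family_abundance(annotations, total_length: int, families=None) -> pd.DataFrame:
    """Log-normalized per-family abundance: log10(1 + count / (length / 1e6)).

    Returns a DataFrame with family, catalytic class, raw count, and the
    log-normalized abundance per Mb, sorted by abundance.  Families listed
    in ``families`` but absent from the annotations appear with abundance 0.
    """
    if total_length <= 0:
        raise ValueError("total_length must be > 0")
    fam_counts: dict[str, int] = {fam: 0 for fam in (families or [])}
    for a in annotations:
        fam_counts[a.family] = fam_counts.get(a.family, 0) + 1
    rows = [
        {
            "family": fam,
            "type_class": family_class(fam),
            "count": cnt,
            "log_abundance_per_mb": float(np.log10(1 + cnt / (total_length / 1e6))),
        }
        for fam, cnt in fam_counts.items()
    ]
    df = pd.DataFrame(rows, columns=["family", "type_class", "count", "log_abundance_per_mb"])
    return df.sort_values("log_abundance_per_mb", ascending=False, ignore_index=True)


def consecutive_duplicates(annotations, max_gap: int = 500) -> dict[str, int]:
    """Count adjacent same-family IS pairs with an intervening gap <= max_gap.

    Annotations are sorted internally by (replicon, start); a run of n
    same-family elements contributes n - 1 pairs.  The gap is measured
    between the end of one element and the start of the next.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    srt = sorted(annotations, key=lambda a: (a.replicon_id, a.start, a.end))
    pairs: dict[str, int] = {}
    for a, b in zip(srt, srt[1:]):
        if (
            a.replicon_id == b.replicon_id
            and a.family == b.family
            and b.start - a.end <= max_gap
        ):
            pairs[a.family] = pairs.get(a.family, 0) + 1
    return pairs


_REP_TOKENS = {"repa", "repb", "repc"}
_TRA_RE = re.compile(r"^tra[a-z0-9]?$")
_PAR_RE = re.compile(r"^par[a-z0-9]?$")


def plasmid_feature_screen(gene_annotations) -> dict:
    """Screen gene annotations for plasmid backbone operons.

    ``gene_annotations`` is an iterable of (id, product_text, (start, end)).
    Matching is by case-insensitive word tokens: repABC requires all of
    repA/repB/repC (or a repABC token), tra requires a tra-operon gene
    token (tra, traA..traZ — not e.g. "transferase"), par likewise
    (par, parA/parB...).  Returns flags plus the matched intervals.
    """
    found_rep: set[str] = set()
    hits: dict[str, list] = {"repABC": [], "tra": [], "par": []}
    for gid, product, interval in gene_annotations:
        tokens = re.split(r"[^a-zA-Z0-9]+", f"{gid} {product}".lower())
        for tok in tokens:
            if not tok:
                continue
            if tok in _REP_TOKENS:
                found_rep.add(tok)
                hits["repABC"].append((gid, tuple(interval)))
            elif tok == "repabc":
                found_rep |= _REP_TOKENS
                hits["repABC"].append((gid, tuple(interval)))
            elif _TRA_RE.match(tok):
                hits["tra"].append((gid, tuple(interval)))
            elif _PAR_RE.match(tok):
                hits["par"].append((gid, tuple(interval)))
    return {
        "repABC_present": found_rep == _REP_TOKENS,
        "tra_present": bool(hits["tra"]),
        "par_present": bool(hits["par"]),
        "matched": hits,
    }
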