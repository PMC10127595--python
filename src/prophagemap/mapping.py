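"""Read placement and per-base coverage tracks.

A deliberately simple seed-and-verify mapper (exact k-mer anchors, full-read
verification with a substitution budget) stands in for an external short-read
aligner so the pipeline is self-contained and testable.  The analysis proper
begins at the coverage track: externally produced BedGraph coverage is an
equal entry point.

Multi-mapped reads — reads whose best placement is tied across several loci,
as happens for identical multi-copy insertion sequences — are resolved by a
configurable policy.  The default, ``random_best``, picks one best locus
uniformly at random (seeded); this is the semantics under which multi-copy
repeats inside a highly covered prophage spray coverage onto every other copy
and create spurious peaks.  ``all_weighted`` instead adds 1/n_best at every
best locus, and ``unique`` discards multi-mapped reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoverageTrack",
    "KmerIndex",
    "Placement",
    "MappingResult",
    "build_index",
    "map_reads",
    "coverage_from_placements",
    "mapped_fraction",
    "read_bedgraph",
    "write_bedgraph",
]

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class CoverageTrack:
    """Per-position read coverage along one replicon (0-based)."""

    replicon_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be >= 0")

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        return self.replicon_id == other.replicon_id and np.array_equal(
            self.values, other.values
        )

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(self.replicon_id, self.values * factor)


@dataclass
class KmerIndex:
    """Exact k-mer index of both strands of a set of replicons.

    Keys are k-mers of the forward sequence and their reverse complements;
    each entry is (replicon_id, forward start, strand).  Circular replicons
    are indexed across the origin.
    """

    k: int
    entries: dict[str, list[tuple[str, int, str]]]
    sequences: dict[str, str]
    circular: dict[str, bool]

    @property
    def lengths(self) -> dict[str, int]:
        return {rid: len(s) for rid, s in self.sequences.items()}

    def n_entries(self) -> int:
        return sum(len(v) for v in self.entries.values())


@dataclass(frozen=True)
class Placement:
    """One read's placement: the chosen locus plus all equally best loci."""

    read_id: str
    replicon_id: str
    start: int
    strand: str
    n_best: int
    chosen_by: str
    read_length: int
    mismatches: int
    best_loci: tuple[tuple[str, int, str], ...] = field(default=())


@dataclass
class MappingResult:
    placements: list[Placement]
    n_reads: int
    policy: str

    @property
    def n_mapped(self) -> int:
        return len(self.placements)

    @property
    def n_unique(self) -> int:
        return sum(1 for p in self.placements if p.n_best == 1)

    @property
    def n_multi(self) -> int:
        return sum(1 for p in self.placements if p.n_best > 1)

    @property
    def n_unmapped(self) -> int:
        return self.n_reads - self.n_mapped

    def summary(self) -> dict[str, int | float | str]:
        return {
            "total_reads": self.n_reads,
            "mapped": self.n_mapped,
            "unique": self.n_unique,
            "multi": self.n_multi,
            "unmapped": self.n_unmapped,
            "mapped_fraction": self.n_mapped / self.n_reads if self.n_reads else float("nan"),
            "policy": self.policy,
        }


def build_index(replicons, k: int = 21) -> KmerIndex:
    """Index every k-mer start of both strands of every replicon.

    ``replicons`` is an iterable of objects with ``id``, ``sequence`` and
    ``circular`` attributes (or (id, sequence, circular) tuples).
    """
    if not (11 <= k <= 31) or k % 2 == 0:
        raise ValueError(f"k must be odd and in [11, 31], got {k}")
    entries: dict[str, list[tuple[str, int, str]]] = {}
    seqs: dict[str, str] = {}
    circ: dict[str, bool] = {}
    for rep in replicons:
        if isinstance(rep, tuple):
            rid, seq, is_circ = rep
        else:
            rid, seq, is_circ = rep.id, rep.sequence, rep.circular
        seqs[rid] = seq
        circ[rid] = bool(is_circ)
        n = len(seq)
        ext = seq + seq[: k - 1] if is_circ else seq
        n_starts = n if is_circ else n - k + 1
        for p in range(max(0, n_starts)):
            kmer = ext[p : p + k]
            entries.setdefault(kmer, []).append((rid, p, "+"))
            entries.setdefault(_revcomp(kmer), []).append((rid, p, "-"))
    return KmerIndex(k, entries, seqs, circ)


def _count_mismatches(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    m = 0
    for x, y in zip(a, b):
        if x != y:
            m += 1
            if m > limit:
                return m
    return m


def map_reads(
    reads,
    index: KmerIndex,
    max_mismatches: int = 2,
    seed: int = 0,
    policy: str = "random_best",
) -> MappingResult:
    """Seed-and-verify placement of every read (paired mates as singletons).

    Anchors each read by exact k-mer lookups at a stride of k, verifies the
    full read against the genome with at most ``max_mismatches``
    substitutions, collects all equally best loci, and chooses one according
    to ``policy``.  Unplaceable reads are counted, not errors.
    """
    if policy not in ("unique", "random_best", "all_weighted"):
        raise ValueError(f"unknown multi-map policy {policy!r}")
    k = index.k
    rng = np.random.default_rng(seed)
    ext_seqs = {
        rid: (seq + seq[: 512 + k] if index.circular[rid] else seq)
        for rid, seq in index.sequences.items()
    }
    lengths = index.lengths

    flat: list[tuple[str, str]] = []
    for r in getattr(reads, "reads", reads):
        flat.append((r.id, r.sequence))
        if getattr(r, "mate", None):
            flat.append((r.id + "/2", r.mate))

    placements: list[Placement] = []
    for rid_read, seq in flat:
        L = len(seq)
        if L < k:
            continue
        rc = _revcomp(seq)
        offsets = list(range(0, L - k + 1, k))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        candidates: set[tuple[str, int, str]] = set()
        for o in offsets:
            for rep_id, pos, strand in index.entries.get(seq[o : o + k], ()):
                n = lengths[rep_id]
                if strand == "+":
                    s = pos - o
                else:
                    s = pos - (L - o - k)
                if index.circular[rep_id]:
                    s %= n
                elif s < 0 or s + L > n:
                    continue
                candidates.add((rep_id, s, strand))
        best: list[tuple[str, int, str]] = []
        best_mm = max_mismatches + 1
        for rep_id, s, strand in candidates:
            ref = ext_seqs[rep_id][s : s + L]
            if len(ref) < L:
                continue
            query = seq if strand == "+" else rc
            mm = _count_mismatches(query, ref, max_mismatches)
            if mm < best_mm:
                best_mm = mm
                best = [(rep_id, s, strand)]
            elif mm == best_mm and mm <= max_mismatches:
                best.append((rep_id, s, strand))
        if best_mm > max_mismatches or not best:
            continue
        best.sort()
        n_best = len(best)
        if n_best == 1:
            chosen, chosen_by = best[0], "unique"
        elif policy == "random_best":
            chosen, chosen_by = best[int(rng.integers(n_best))], "random_best"
        else:
            chosen, chosen_by = best[0], policy
        placements.append(
            Placement(
                read_id=rid_read,
                replicon_id=chosen[0],
                start=chosen[1],
                strand=chosen[2],
                n_best=n_best,
                chosen_by=chosen_by,
                read_length=L,
                mismatches=best_mm,
                best_loci=tuple(best),
            )
        )
    return MappingResult(placements, len(flat), policy)


def coverage_from_placements(
    placements,
    replicon_lengths: dict[str, int],
    policy: str = "random_best",
    circular: dict[str, bool] | None = None,
) -> dict[str, CoverageTrack]:
    """Accumulate per-base coverage from placements under a multi-map policy.

    ``unique``/``random_best`` add 1 over the chosen read footprint (unique
    drops multi-mapped reads); ``all_weighted`` adds 1/n_best at every best
    locus.  Circular wrap is honored; a placement running past the end of a
    linear replicon is an error.
    """
    if policy not in ("unique", "random_best", "all_weighted"):
        raise ValueError(f"unknown multi-map policy {policy!r}")
    circular = circular or {}
    diffs = {rid: np.zeros(n + 1) for rid, n in replicon_lengths.items()}

    def add(rid: str, start: int, length: int, w: float) -> None:
        n = replicon_lengths[rid]
        if start >= n or start < 0:
            raise ValueError(f"placement start {start} outside replicon {rid!r}")
        end = start + length
        if end <= n:
            diffs[rid][start] += w
            diffs[rid][end] -= w
        elif circular.get(rid, False):
            diffs[rid][start] += w
            diffs[rid][n] -= w
            diffs[rid][0] += w
            diffs[rid][end - n] -= w
        else:
            raise ValueError(
                f"placement [{start}, {end}) beyond end of linear replicon {rid!r}"
            )

    for p in placements:
        if policy == "all_weighted":
            w = 1.0 / p.n_best
            for rid, s, _ in p.best_loci:
                add(rid, s, p.read_length, w)
        else:
            if policy == "unique" and p.n_best > 1:
                continue
            add(p.replicon_id, p.start, p.read_length, 1.0)

    return {
        rid: CoverageTrack(rid, np.cumsum(d[:-1])) for rid, d in diffs.items()
    }


def mapped_fraction(placements, reads) -> float:
    """Placed reads / total reads, in [0, 1].  Errors on an empty read set."""
    if isinstance(placements, MappingResult):
        n_placed, n_total = placements.n_mapped, placements.n_reads
    else:
        n_placed = len(placements)
        n_total = len(getattr(reads, "reads", reads))
        n_total += sum(
            1 for r in getattr(reads, "reads", reads) if getattr(r, "mate", None)
        )
    if n_total == 0:
        raise ValueError("mapped_fraction of an empty read set is undefined")
    return n_placed / n_total


def write_bedgraph(tracks, path) -> None:
    """Write coverage tracks as BedGraph (0-based half-open).

    Adjacent equal-valued runs are merged; zero runs are written too, so a
    round trip preserves the track exactly, including its length.
    """
    if isinstance(tracks, CoverageTrack):
        tracks = [tracks]
    with open(path, "w") as fh:
        for t in tracks:
            v = t.values
            if v.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [v.size]])
            for s, e in zip(starts, ends):
                val = v[s]
                sval = f"{int(val)}" if float(val).is_integer() else f"{val:g}"
                fh.write(f"{t.replicon_id}\t{s}\t{e}\t{sval}\n")


def read_bedgraph(path, lengths: dict[str, int] | None = None) -> dict[str, CoverageTrack]:
    """Read BedGraph coverage (0-based half-open, non-overlapping intervals).

    Gaps are filled with 0.  Track length is the declared length when
    ``lengths`` is given, otherwise the maximum end coordinate seen.
    Overlapping intervals, negative values and out-of-range coordinates are
    rejected with their line number.
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 BedGraph columns, got {len(parts)}")
            rid, s_s, e_s, v_s = parts
            try:
                s, e, v = int(s_s), int(e_s), float(v_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: unparseable coordinates/value") from exc
            if e <= s:
                raise ValueError(f"{path}:{ln}: end {e} <= start {s}")
            if v < 0:
                raise ValueError(f"{path}:{ln}: negative coverage value {v}")
            if lengths is not None:
                if rid not in lengths:
                    raise ValueError(f"{path}:{ln}: unknown replicon {rid!r}")
                if e > lengths[rid]:
                    raise ValueError(
                        f"{path}:{ln}: end {e} beyond declared length {lengths[rid]}"
                    )
            intervals.setdefault(rid, []).append((s, e, v))

    out: dict[str, CoverageTrack] = {}
    for rid, ivs in intervals.items():
        ivs.sort()
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{path}: overlapping BedGraph intervals on {rid!r} at {s2} < {e1}"
                )
        n = lengths[rid] if lengths is not None else ivs[-1][1]
        values = np.zeros(n)
        for s, e, v in ivs:
            values[s:e] = v
        out[rid] = CoverageTrack(rid, values)
    if lengths is not None:
        for rid, n in lengths.items():
            out.setdefault(rid, CoverageTrack(rid, np.zeros(n)))
    return out
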