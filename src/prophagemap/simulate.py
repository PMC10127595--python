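"""Synthetic lysogen genomes, induced-phage read sets, and culture count tables.

The simulator emulates the statistical structure of a spontaneously induced
phage sequencing experiment on a lysogenic bacterium: a large circular
replicon carrying one or two integrated prophages, an induced-phage DNA
fraction whose read coverage is enormously enriched over the prophage
("core"), moderately elevated over a one-sided flanking region (the
signature of headful over-packaging / specialized transduction), and at
background depth elsewhere; multi-copy identical insertion sequences (IS)
that create spurious coverage peaks under multi-mapped read assignment;
and a small contaminant read fraction that maps nowhere.

Coordinates are 0-based half-open everywhere in this module.  Replicons are
circular by default: reads may wrap the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .growth import CountSeries
from .mapping import CoverageTrack

__all__ = [
    "Replicon",
    "PlantedProphage",
    "PlantedIS",
    "ISSpec",
    "GenomeModel",
    "ReadSimParams",
    "Read",
    "ReadTruth",
    "ReadSet",
    "GrowthParams",
    "simulate_genome",
    "expected_coverage_profile",
    "sample_coverage_track",
    "simulate_phage_reads",
    "simulate_host_reads",
    "simulate_growth_counts",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# fixed-seed contaminant sequence: mimics sequencing-kit contaminants
# (reads from unrelated taxa) that map nowhere on the host genome
_CONTAMINANT_SEED = 987654321
_CONTAMINANT_LEN = 50_000


@dataclass(frozen=True)
class Replicon:
    """One replicon (chromosome or plasmid) of the simulated lysogen."""

    id: str
    sequence: str
    circular: bool = True

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PlantedProphage:
    """Ground-truth record of an integrated prophage and its packaging profile.

    ``core_rate`` is the expected per-base coverage of the prophage interval in
    the phage fraction; ``flank_rate``/``flank_extent`` describe the moderately
    over-packaged host DNA abutting exactly one prophage boundary
    (``flank_side``).  ``flank_decay`` is ``"flat"`` (constant ``flank_rate``
    over the extent) or ``"geometric"`` (``flank_rate * decay_per_kb**(d/1000)``
    at distance ``d`` from the prophage edge).
    """

    start: int
    end: int
    core_rate: float
    replicon_id: str = "chr"
    flank_side: str = "none"  # {left, right, none}
    flank_rate: float = 0.0
    flank_extent: int = 0
    flank_decay: str = "flat"  # {flat, geometric}
    decay_per_kb: float = 0.5

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"prophage end must exceed start: [{self.start}, {self.end})")
        if self.flank_side not in ("left", "right", "none"):
            raise ValueError(f"flank_side must be left/right/none, got {self.flank_side!r}")
        if self.flank_decay not in ("flat", "geometric"):
            raise ValueError(f"flank_decay must be flat/geometric, got {self.flank_decay!r}")
        if self.flank_side != "none":
            if not (self.core_rate > self.flank_rate > 0):
                raise ValueError(
                    "flanked prophage requires core_rate > flank_rate > 0, got "
                    f"core_rate={self.core_rate}, flank_rate={self.flank_rate}"
                )
            if self.flank_extent <= 0:
                raise ValueError("flank_extent must be positive when a flank is present")

    @property
    def length(self) -> int:
        return self.end - self.start

    def flank_interval(self) -> tuple[int, int] | None:
        """Half-open interval of the flank, abutting one prophage boundary."""
        if self.flank_side == "none":
            return None
        if self.flank_side == "left":
            return (self.start - self.flank_extent, self.start)
        return (self.end, self.end + self.flank_extent)


@dataclass(frozen=True)
class PlantedIS:
    """Ground-truth record of one planted IS copy."""

    start: int
    end: int
    family: str
    replicon_id: str = "chr"
    inside_prophage: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ISSpec:
    """Request to plant one IS copy; all copies of a family share one sequence."""

    start: int
    family: str
    length: int


@dataclass
class GenomeModel:
    """Replicon sequences plus the full ground truth of planted features."""

    replicons: list[Replicon]
    prophages: list[PlantedProphage] = field(default_factory=list)
    is_copies: list[PlantedIS] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = {r.id: len(r) for r in self.replicons}
        for p in self.prophages:
            lo, hi = p.start, p.end
            fi = p.flank_interval()
            if fi is not None:
                lo, hi = min(lo, fi[0]), max(hi, fi[1])
            if p.replicon_id not in lengths:
                raise ValueError(f"prophage on unknown replicon {p.replicon_id!r}")
            if lo < 0 or hi > lengths[p.replicon_id]:
                raise ValueError(
                    f"prophage (with flank) [{lo}, {hi}) exceeds replicon "
                    f"{p.replicon_id!r} of length {lengths[p.replicon_id]}"
                )
        for rid in lengths:
            spans = sorted(
                (p.start, p.end) for p in self.prophages if p.replicon_id == rid
            )
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping prophages on {rid!r}: [{s1}, {e1}) and [{s2}, {e2})"
                    )
        for c in self.is_copies:
            if c.replicon_id not in lengths:
                raise ValueError(f"IS copy on unknown replicon {c.replicon_id!r}")
            if c.start < 0 or c.end > lengths[c.replicon_id]:
                raise ValueError(f"IS copy [{c.start}, {c.end}) exceeds {c.replicon_id!r}")

    @property
    def lengths(self) -> dict[str, int]:
        return {r.id: len(r) for r in self.replicons}

    def replicon(self, rid: str) -> Replicon:
        for r in self.replicons:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def is_sequences(self) -> dict[str, str]:
        """Family -> shared IS sequence (validated identical across copies)."""
        out: dict[str, str] = {}
        for c in self.is_copies:
            seq = self.replicon(c.replicon_id).sequence[c.start : c.end]
            if c.family in out and out[c.family] != seq:
                raise ValueError(f"IS family {c.family!r} copies are not identical")
            out.setdefault(c.family, seq)
        return out


@dataclass(frozen=True)
class ReadSimParams:
    """Phage-fraction read simulation parameters.

    ``background_rate`` is the expected per-base coverage of non-enriched host
    DNA in the phage fraction (the residual host DNA signal);
    ``contaminant_fraction`` is the expected proportion of reads drawn from an
    unrelated fixed random sequence disjoint from the genome.
    """

    read_length: int = 100
    error_rate: float = 0.0
    background_rate: float = 5.0
    contaminant_fraction: float = 0.0
    paired: bool = False
    insert_size: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if not (0 <= self.contaminant_fraction < 1):
            raise ValueError("contaminant_fraction must be in [0, 1)")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    mate: str | None = None


@dataclass(frozen=True)
class ReadTruth:
    label: str  # {core, flank, background, contaminant}
    replicon_id: str | None
    start: int | None
    strand: str | None


@dataclass
class ReadSet:
    """Simulated reads with optional per-read ground-truth origin labels."""

    reads: list[Read]
    truth: list[ReadTruth] | None = None
    read_length: int = 100

    def __post_init__(self) -> None:
        if self.truth is not None and len(self.truth) != len(self.reads):
            raise ValueError("truth labels, when present, must cover every read")

    def __len__(self) -> int:
        return len(self.reads)

    def label_counts(self) -> dict[str, int]:
        if self.truth is None:
            return {}
        out: dict[str, int] = {}
        for t in self.truth:
            out[t.label] = out.get(t.label, 0) + 1
        return out


@dataclass(frozen=True)
class GrowthParams:
    """Culture-kinetics simulation parameters.

    ``induction_yield`` is phage-like particles (PLPs) produced per cell per
    hour by spontaneous induction; ``phage_decay`` is the first-order PLP loss
    rate per hour.  Default timepoints follow a 48-h batch-culture sampling
    design (0, 6, 12, 24, 36, 48 h).
    """

    initial_cells: float = 1e6
    doubling_time: float = 7.1
    induction_yield: float = 0.05
    phage_decay: float = 0.0
    initial_plps: float = 1e5
    carrying_capacity: float | None = None
    timepoints: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 36.0, 48.0)
    noise: str | None = "lognormal"  # {lognormal, poisson, None}
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_cells <= 0 or self.doubling_time <= 0:
            raise ValueError("initial_cells and doubling_time must be positive")
        if self.induction_yield < 0 or self.phage_decay < 0 or self.initial_plps < 0:
            raise ValueError("rates and initial counts must be >= 0")
        t = np.asarray(self.timepoints, dtype=float)
        if t.size == 0 or t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing, starting at 0")
        if self.noise not in (None, "lognormal", "poisson"):
            raise ValueError("noise must be lognormal, poisson, or None")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def simulate_genome(
    length: int,
    gc: float = 0.635,
    prophage_specs: list[PlantedProphage] | None = None,
    is_specs: list[ISSpec] | None = None,
    seed: int = 0,
    replicon_id: str = "chr",
    circular: bool = True,
) -> GenomeModel:
    """Generate a random replicon with planted prophages and IS copies.

    Bases are i.i.d. at the requested GC content (default 0.635, typical of
    rhizobial genomes).  All copies of one IS family are written with an
    identical sequence, which is what creates multi-mapping artifacts
    downstream.  Deterministic for a fixed seed.
    """
    if length < 10_000:
        raise ValueError("replicon length must be >= 10 kb")
    if not (0 < gc < 1):
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    seq = np.frombuffer(_random_sequence(rng, length, gc).encode(), dtype="S1").copy()

    prophages = [replace(p, replicon_id=replicon_id) for p in (prophage_specs or [])]

    fam_seqs: dict[str, str] = {}
    is_copies: list[PlantedIS] = []
    for spec in is_specs or []:
        if spec.start < 0 or spec.start + spec.length > length:
            raise ValueError(f"IS spec at {spec.start} (+{spec.length}) exceeds replicon length {length}")
        if spec.family not in fam_seqs:
            fam_seqs[spec.family] = _random_sequence(rng, spec.length, gc)
        fam = fam_seqs[spec.family]
        if len(fam) != spec.length:
            raise ValueError(f"IS family {spec.family!r} copies must share one length")
        seq[spec.start : spec.start + spec.length] = np.frombuffer(fam.encode(), dtype="S1")
        inside = any(
            p.start <= spec.start and spec.start + spec.length <= p.end for p in prophages
        )
        is_copies.append(
            PlantedIS(spec.start, spec.start + spec.length, spec.family, replicon_id, inside)
        )

    replicon = Replicon(replicon_id, seq.tobytes().decode("ascii"), circular)
    return GenomeModel([replicon], prophages, is_copies, seed)


def expected_coverage_profile(
    genome: GenomeModel, params: ReadSimParams
) -> dict[str, CoverageTrack]:
    """Analytic per-base expected coverage of the phage fraction (no sampling).

    Background everywhere, ``core_rate`` over prophage cores, and the flank
    profile over flank intervals.  Serves as the test oracle for the read
    simulator and as the noise-free input to the caller.
    """
    out: dict[str, CoverageTrack] = {}
    for rep in genome.replicons:
        rates = np.full(len(rep), float(params.background_rate))
        for p in genome.prophages:
            if p.replicon_id != rep.id:
                continue
            rates[p.start : p.end] = p.core_rate
            fi = p.flank_interval()
            if fi is not None:
                s, e = fi
                if p.flank_decay == "flat":
                    rates[s:e] = p.flank_rate
                else:
                    # distance from the prophage edge, in bp
                    d = np.arange(e - s, dtype=float)
                    if p.flank_side == "left":
                        d = d[::-1] + 1
                    else:
                        d = d + 1
                    rates[s:e] = p.flank_rate * p.decay_per_kb ** (d / 1000.0)
        out[rep.id] = CoverageTrack(rep.id, rates)
    return out


def sample_coverage_track(
    genome: GenomeModel, params: ReadSimParams, seed: int
) -> dict[str, CoverageTrack]:
    """Poisson-sample a per-base coverage track from the expected profile.

    Desk-scale shortcut: equivalent in per-base distribution to simulating and
    mapping reads, minus read-length edge ramps at rate steps.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for rid, track in expected_coverage_profile(genome, params).items():
        out[rid] = CoverageTrack(rid, rng.poisson(track.values).astype(float))
    return out


def _position_class(genome: GenomeModel, rid: str, length: int) -> np.ndarray:
    """Per-position truth label codes: 0 background, 1 flank, 2 core."""
    cls = np.zeros(length, dtype=np.int8)
    for p in genome.prophages:
        if p.replicon_id != rid:
            continue
        fi = p.flank_interval()
        if fi is not None:
            cls[fi[0] : fi[1]] = 1
        cls[p.start : p.end] = 2
    return cls


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _apply_errors(rng: np.random.Generator, seqs: list[str], e: float) -> list[str]:
    if e <= 0:
        return seqs
    out = []
    for s in seqs:
        n_err = rng.binomial(len(s), e)
        if n_err == 0:
            out.append(s)
            continue
        arr = np.frombuffer(s.encode(), dtype="S1").copy()
        pos = rng.choice(len(s), size=n_err, replace=False)
        for p in pos:
            current = arr[p]
            choices = _BASES[_BASES != current]
            arr[p] = rng.choice(choices)
        out.append(arr.tobytes().decode("ascii"))
    return out


def _sample_reads_from_rates(
    genome: GenomeModel,
    rates: dict[str, np.ndarray],
    params: ReadSimParams,
    labels: dict[str, np.ndarray] | None,
    cap: int,
    id_prefix: str,
) -> ReadSet:
    """Sample reads with per-position start intensity rate/L (circular wrap)."""
    L = params.read_length
    rng = np.random.default_rng(params.seed)
    label_names = {0: "background", 1: "flank", 2: "core"}

    frag = params.insert_size if params.paired else L
    per_frag_bases = 2 * L if params.paired else L
    expected = sum(r.sum() / per_frag_bases for r in rates.values())
    expected_total = expected / max(1e-12, 1 - params.contaminant_fraction)
    n_reads_factor = 2 if params.paired else 1
    if expected_total * n_reads_factor > cap:
        raise ValueError(
            f"expected read count {expected_total * n_reads_factor:,.0f} exceeds cap {cap:,}; "
            "reduce depth or raise the cap explicitly"
        )

    reads: list[Read] = []
    truth: list[ReadTruth] = []
    for rep in genome.replicons:
        rate = rates[rep.id]
        intensity = rate / per_frag_bases
        total = intensity.sum()
        if total <= 0:
            continue
        n = rng.poisson(total)
        if n == 0:
            continue
        starts = rng.choice(len(rate), size=n, p=intensity / total)
        strands = rng.choice(np.array(["+", "-"]), size=n)
        ext = rep.sequence + rep.sequence[: frag + 1] if rep.circular else rep.sequence
        cls = labels[rep.id] if labels is not None else None
        seqs: list[str] = []
        kept_idx: list[int] = []
        for i, (s, st) in enumerate(zip(starts, strands)):
            if not rep.circular and s + frag > len(rep):
                continue  # linear replicon: truncated fragments dropped
            fragment = ext[s : s + frag]
            seqs.append(fragment)
            kept_idx.append(i)
        for j, i in enumerate(kept_idx):
            s, st = int(starts[i]), strands[i]
            fragment = seqs[j]
            fwd = fragment if st == "+" else _revcomp(fragment)
            r1 = fwd[:L]
            label = label_names[int(cls[s % len(rate)])] if cls is not None else "background"
            if params.paired:
                r2 = _revcomp(fwd)[:L]
                r1e, r2e = _apply_errors(rng, [r1, r2], params.error_rate)
                reads.append(Read(f"{id_prefix}{len(reads)}", r1e, r2e))
            else:
                reads.append(Read(f"{id_prefix}{len(reads)}", _apply_errors(rng, [r1], params.error_rate)[0]))
            truth.append(ReadTruth(label, rep.id, s, st))

    if params.contaminant_fraction > 0:
        crng = np.random.default_rng(_CONTAMINANT_SEED)
        cont = _random_sequence(crng, _CONTAMINANT_LEN, 0.5)
        n_cont = rng.poisson(expected * params.contaminant_fraction / (1 - params.contaminant_fraction))
        cstarts = rng.integers(0, _CONTAMINANT_LEN - L, size=n_cont)
        for s in cstarts:
            seq = cont[s : s + L]
            seq = _apply_errors(rng, [seq], params.error_rate)[0]
            if params.paired:
                reads.append(Read(f"{id_prefix}{len(reads)}", seq, _revcomp(seq)))
            else:
                reads.append(Read(f"{id_prefix}{len(reads)}", seq))
            truth.append(ReadTruth("contaminant", None, None, None))

    return ReadSet(reads, truth, L)


def simulate_phage_reads(
    genome: GenomeModel, params: ReadSimParams, cap: int = 5_000_000
) -> ReadSet:
    """Simulate the induced-phage sequencing fraction.

    Per-base expected coverage follows :func:`expected_coverage_profile`:
    ``core_rate`` over prophage cores, the flank profile over flanks, the
    background rate elsewhere.  Substitution errors at ``error_rate``;
    contaminant reads appended at the requested expected proportion; every
    read carries a truth label.  Refuses runs whose expected read count
    exceeds ``cap``.
    """
    profile = expected_coverage_profile(genome, params)
    rates = {rid: t.values for rid, t in profile.items()}
    labels = {rep.id: _position_class(genome, rep.id, len(rep)) for rep in genome.replicons}
    return _sample_reads_from_rates(genome, rates, params, labels, cap, "phage_")


def simulate_host_reads(
    genome: GenomeModel,
    depth: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    cap: int = 5_000_000,
) -> ReadSet:
    """Simulate the host-genome control fraction: uniform coverage, no enrichment."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    params = ReadSimParams(
        read_length=read_length, error_rate=error_rate, background_rate=depth, seed=seed
    )
    rates = {rep.id: np.full(len(rep), float(depth)) for rep in genome.replicons}
    return _sample_reads_from_rates(genome, rates, params, None, cap, "host_")


def simulate_growth_counts(params: GrowthParams) -> CountSeries:
    """Simulate a batch-culture time course of cells/mL and PLPs/mL.

    Cells grow exponentially with the given doubling time (optionally capped
    at a carrying capacity); PLPs accumulate at ``induction_yield`` per
    cell-hour minus first-order decay, integrated numerically.  Observed
    counts are noise-perturbed (lognormal or Poisson) unless noise is None.
    """
    from scipy.integrate import solve_ivp

    t = np.asarray(params.timepoints, dtype=float)
    mu = np.log(2.0) / params.doubling_time

    def cells(tt: float) -> float:
        b = params.initial_cells * np.exp(mu * tt)
        if params.carrying_capacity is not None:
            b = min(b, params.carrying_capacity)
        return b

    def dP(tt, p):
        return params.induction_yield * cells(tt) - params.phage_decay * p[0]

    sol = solve_ivp(dP, (0.0, t[-1]), [params.initial_plps], t_eval=t, rtol=1e-8, atol=1e-6)
    B = np.array([cells(tt) for tt in t])
    P = sol.y[0]

    rng = np.random.default_rng(params.seed)
    if params.noise == "lognormal":
        sig = params.noise_sigma
        B = B * rng.lognormal(-sig**2 / 2, sig, size=B.size)
        P = P * rng.lognormal(-sig**2 / 2, sig, size=P.size)
    elif params.noise == "poisson":
        B = rng.poisson(B).astype(float)
        P = rng.poisson(P).astype(float)
    return CountSeries(timepoints=t, cells=B, plps=P, replicate="sim")
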