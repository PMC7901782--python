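"""Synthetic study generator for nitrogen-limited aquaponic systems.

Every input the pipeline consumes can be generated here with the statistical
structure the downstream analysis assumes: a small 16S reference database
with controlled within- and between-genus divergence, genus-level community
profiles per (tank, compartment, day), noisy long reads with a nanopore-like
error regime (predicted median quality ~15 but realized error above 10%),
a k-mer alignment scorer standing in for a real long-read aligner at desk
scale, tank water-chemistry time series with an ammonia -> nitrite -> nitrate
cascade, and per-plant growth phenotypes coupled to the root community.

All generators are deterministic given (parameters, seed), and read/community
truth tags are emitted so recovery tests need no re-derivation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord, ReadRecord, TaxonomyEntry

__all__ = [
    "ReferenceDB",
    "ErrorModel",
    "StudyDesign",
    "CommunityProfile",
    "DEFAULT_GENERA",
    "generate_reference_db",
    "default_reference_db",
    "simulate_communities",
    "simulate_reads",
    "score_alignments",
    "simulate_water_chemistry",
    "simulate_phenotypes",
    "simulate_validation_tables",
]

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
COMPARTMENTS = ("biofilter", "root", "feces")
SAMPLING_DAYS = (0, 21, 61)

#: Default genus roster. The first is the pathogen-like genus enriched in
#: EIT rhizospheres, the second the diazotroph-like genus enriched in CIT.
DEFAULT_GENERA = ("Pseudomonas", "Rahnella", "Serratia", "Aeromonas", "Rhodanobacter")


@dataclass(frozen=True)
class ReferenceDB:
    """A toy full-length 16S reference set with genus structure."""

    sequences: dict[str, str]
    taxonomy: dict[str, TaxonomyEntry]
    genera: dict[str, tuple[str, ...]]  # genus -> ref_ids

    @property
    def ref_ids(self) -> list[str]:
        return sorted(self.sequences)

    def genus_of(self, ref_id: str) -> str | None:
        return self.taxonomy[ref_id].genus


@dataclass(frozen=True)
class ErrorModel:
    """Per-base sequencing noise and the predicted-quality distribution.

    The default regime matches long-read amplicon data where the basecaller
    predicts a median Phred of ~15 (3% error) while the realized error rate
    exceeds 10%: substitution 0.06, insertion 0.03, deletion 0.03. Predicted
    qualities are a two-component mixture (mostly decent reads plus a
    low-quality tail) so the expected-error filter has something to remove.
    """

    substitution: float = 0.06
    insertion: float = 0.03
    deletion: float = 0.03
    q_good: float = 17.0
    q_bad: float = 7.0
    bad_read_fraction: float = 0.30
    q_sd: float = 3.0
    n_rate: float = 0.0005

    def __post_init__(self) -> None:
        for name in ("substitution", "insertion", "deletion"):
            r = getattr(self, name)
            if not 0 <= r < 1:
                raise ValueError(f"{name} rate must be in [0, 1), got {r}")

    @property
    def total_error(self) -> float:
        return self.substitution + self.insertion + self.deletion

    def zeroed(self) -> "ErrorModel":
        """A noiseless copy (exact reads, flat high quality)."""
        return replace(self, substitution=0.0, insertion=0.0, deletion=0.0,
                       bad_read_fraction=0.0, q_sd=0.0, n_rate=0.0, q_good=40.0)


@dataclass(frozen=True)
class StudyDesign:
    """The six-tank, two-arm aquaponics experiment layout.

    Tanks 1-3 receive the commercial inoculum (CIT), tanks 4-6 the
    established-system inoculum (EIT). Three compartments are sampled at
    days 0, 21 and 61. Effect sizes couple the root community to plant
    growth; fish deaths default to one per arm (orthogonal to inoculum)
    with the CIT death driving a transient nitrate spike.
    """

    tanks: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    cit_tanks: tuple[int, ...] = (1, 2, 3)
    eit_tanks: tuple[int, ...] = (4, 5, 6)
    compartments: tuple[str, ...] = COMPARTMENTS
    sampling_days: tuple[int, ...] = SAMPLING_DAYS
    fish_deaths: Mapping[int, int] = field(default_factory=lambda: {3: 1, 6: 1})
    nitrate_spike_tank: int | None = 3
    death_day: int = 35
    pathogen_genus: str = DEFAULT_GENERA[0]
    diazotroph_genus: str = DEFAULT_GENERA[1]
    # multiplicative growth penalties/bonuses per unit root relative abundance
    pathogen_growth_effect: float = 0.9
    diazotroph_growth_effect: float = 0.8
    plants_per_tank: int = 13
    library_size_range: tuple[int, int] = (9_800, 125_000)
    dirichlet_concentration: float = 200.0
    missing_samples: frozenset[tuple[int, str, int]] = frozenset({(2, "feces", 21)})
    chemistry_shift: Mapping[str, float] = field(default_factory=dict)  # analyte -> EIT shift

    def __post_init__(self) -> None:
        if set(self.cit_tanks) | set(self.eit_tanks) != set(self.tanks):
            raise ValueError("cit_tanks and eit_tanks must partition tanks")
        if len(self.cit_tanks) != 3 or len(self.eit_tanks) != 3:
            raise ValueError("exactly 3 tanks per inoculum arm")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("invalid library_size_range")
        for eff in (self.pathogen_growth_effect, self.diazotroph_growth_effect):
            if not np.isfinite(eff):
                raise ValueError("effect sizes must be finite")

    def inoculum_of(self, tank: int) -> str:
        if tank in self.cit_tanks:
            return "CIT"
        if tank in self.eit_tanks:
            return "EIT"
        return "initial"  # shared pre-treatment samples carry tank id 0

    def deaths_of(self, tank: int) -> int:
        return int(self.fish_deaths.get(tank, 0))

    def desk_scale(self, factor: float = 8.0) -> "StudyDesign":
        """Shrink library sizes by ``factor`` for fast test-scale runs.

        The maximum shrinks faster than the minimum (compressing the range)
        so that a rarefaction depth scaled by 1/factor remains feasible in
        every sample after the expected ~30% QC loss, preserving the
        depth-to-minimum-library relationship of the full-scale analysis.
        """
        lo, hi = self.library_size_range
        new_lo = max(200, int(lo / factor**0.75))
        new_hi = max(2 * new_lo, int(hi / factor**1.7))
        return replace(self, library_size_range=(new_lo, new_hi))


@dataclass(frozen=True)
class CommunityProfile:
    """Genus-level relative abundances for one sample, with identity metadata."""

    sample_id: str
    tank: int
    compartment: str
    day: int
    abundances: dict[str, float]  # genus -> relative abundance, sums to 1

    def __post_init__(self) -> None:
        vals = np.array(list(self.abundances.values()))
        if (vals < 0).any():
            raise ValueError("negative relative abundance")
        total = vals.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, expected 1")


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position independently with probability ``rate``."""
    out = arr.copy()
    mask = rng.random(arr.size) < rate
    n = int(mask.sum())
    if n:
        # map current base to one of the three other bases
        idx = np.searchsorted(_BASES, out[mask])
        shift = rng.integers(1, 4, size=n)
        out[mask] = _BASES[(idx + shift) % 4]
    return out


def generate_reference_db(
    n_genera: int = 5,
    seqs_per_genus: int = 3,
    within_genus_divergence: float = 0.02,
    between_genus_divergence: float = 0.20,
    seed: int = 0,
    length: int = 1490,
    genus_names: Sequence[str] | None = None,
) -> ReferenceDB:
    """Generate a small 16S-like reference database with genus structure.

    Sequences descend from a single root: genus ancestors are mutated at
    ``between_genus_divergence / 2`` from the root, members at
    ``within_genus_divergence / 2`` from their ancestor, so realized pairwise
    divergences within a genus sit well below those between genera (checked
    on the instance). Deterministic given the seed.
    """
    if n_genera < 2:
        raise ValueError("n_genera must be >= 2")
    if seqs_per_genus < 2:
        raise ValueError("need >=2 sequences per genus so multi-mapping ambiguity exists")
    if not 0 < within_genus_divergence < between_genus_divergence < 0.5:
        raise ValueError(
            "require 0 < within_genus_divergence < between_genus_divergence < 0.5"
        )
    if not 1300 <= length <= 1600:
        raise ValueError("reference length must be within 1.3-1.6 kbp")
    if genus_names is None:
        if n_genera <= len(DEFAULT_GENERA):
            genus_names = DEFAULT_GENERA[:n_genera]
        else:
            genus_names = tuple(DEFAULT_GENERA) + tuple(
                f"Genus{i:03d}" for i in range(n_genera - len(DEFAULT_GENERA))
            )
    rng = np.random.default_rng(seed)
    root = _BASES[rng.integers(0, 4, size=length)]
    sequences: dict[str, str] = {}
    taxonomy: dict[str, TaxonomyEntry] = {}
    genera: dict[str, tuple[str, ...]] = {}
    for g, genus in enumerate(genus_names):
        ancestor = _mutate(root, between_genus_divergence / 2, rng)
        members = []
        for s in range(seqs_per_genus):
            ref_id = f"{genus}_{s + 1:02d}"
            seq = _mutate(ancestor, within_genus_divergence / 2, rng)
            sequences[ref_id] = _array_to_seq(seq)
            lineage = (
                "Bacteria",
                f"Phylum{g % 3}",
                f"Class{g % 3}",
                f"Order{g}",
                f"Family{g}",
                genus,
                f"{genus} sp{s + 1}",
            )
            taxonomy[ref_id] = TaxonomyEntry(ref_id, lineage)
            members.append(ref_id)
        genera[genus] = tuple(members)
    db = ReferenceDB(sequences, taxonomy, genera)
    _check_divergence_ordering(db)
    return db


def _check_divergence_ordering(db: ReferenceDB) -> None:
    """Assert realized within-genus divergences fall below between-genus ones."""
    arrs = {r: _seq_to_array(s) for r, s in db.sequences.items()}
    within, between = [], []
    refs = db.ref_ids
    for i, a in enumerate(refs):
        for b in refs[i + 1:]:
            d = float(np.mean(arrs[a] != arrs[b]))
            if db.genus_of(a) == db.genus_of(b):
                within.append(d)
            else:
                between.append(d)
    if within and between and max(within) >= min(between):
        raise ValueError(
            f"realized divergence ordering violated: max within {max(within):.3f} "
            f">= min between {min(between):.3f}"
        )


def default_reference_db(seed: int = 0) -> ReferenceDB:
    """The 5-genus x 3-reference database used throughout the synthetic study."""
    return generate_reference_db(seed=seed)


# ---------------------------------------------------------------------------
# Community profiles


def _genus_targets(
    design: StudyDesign, genera: Sequence[str], tank: int, compartment: str, day: int
) -> np.ndarray:
    """Mean genus fractions for one sample before Dirichlet noise."""
    inoc = design.inoculum_of(tank)
    day_frac = design.sampling_days.index(day) / max(1, len(design.sampling_days) - 1)
    path, diaz = design.pathogen_genus, design.diazotroph_genus
    rest = [g for g in genera if g not in (path, diaz)]
    # real communities are uneven: geometric tilt over the background genera
    rest_w = np.array([0.6**i for i in range(len(rest))])
    rest_w /= rest_w.sum()

    def compose(p_path: float, p_diaz: float) -> np.ndarray:
        out = np.zeros(len(genera))
        remaining = max(0.0, 1.0 - p_path - p_diaz)
        k = 0
        for i, g in enumerate(genera):
            if g == path:
                out[i] = p_path
            elif g == diaz:
                out[i] = p_diaz
            else:
                out[i] = remaining * rest_w[k]
                k += 1
        return out

    if compartment == "biofilter":
        if day == min(design.sampling_days):
            # day 0 is the inoculum itself: the commercial product is
            # dominated by a denitrifier-like genus, the established-system
            # transfer already carries the pathogen-like genus
            out = compose(0.02 if inoc == "CIT" else 0.15, 0.03)
            if inoc == "CIT" and "Rhodanobacter" in genera:
                j = list(genera).index("Rhodanobacter")
                out[j] = 0.0
                out *= 0.5 / out.sum()
                out[j] = 0.5  # dominant in the commercial mix
            return out
        # pathogen accumulates 5% -> ~28% in every biofilter regardless of arm
        return compose(0.05 + 0.23 * day_frac, 0.08)
    if compartment == "root":
        if inoc == "EIT":
            p_path = 0.02 + (0.65 - 0.02) * day_frac  # 50-80% band at day 61
            p_diaz = 0.03
        else:
            p_path = 0.02 + (0.10 - 0.02) * day_frac  # stays < 20%
            p_diaz = 0.04 + (0.30 - 0.04) * day_frac
        return compose(p_path, p_diaz)
    # feces: gut-like community, low pathogen fraction
    return compose(0.06, 0.12)


def simulate_communities(
    design: StudyDesign, db: ReferenceDB, seed: int = 0
) -> list[CommunityProfile]:
    """Genus-level profiles per (tank, compartment, day) with Dirichlet noise.

    EIT root profiles carry the pathogen-like genus at 50-80% by day 61 while
    CIT roots stay below 20%; biofilters in both arms carry it at 5-30%.
    Designed missing samples are omitted.
    """
    genera = list(db.genera)
    for g in (design.pathogen_genus, design.diazotroph_genus):
        if g not in genera:
            raise ValueError(f"designed genus {g!r} absent from reference database")
    rng = np.random.default_rng(seed)
    profiles = []
    day0 = min(design.sampling_days)
    # plants enter the tanks weeks after inoculation: the day-0 root sample
    # is a single shared rockwool sample, not one per tank (tank id 0)
    mean = _genus_targets(design, genera, design.tanks[0], "root", day0)
    mean = np.clip(mean, 1e-4, None)
    mean /= mean.sum()
    draw = rng.dirichlet(mean * design.dirichlet_concentration)
    draw /= draw.sum()
    profiles.append(
        CommunityProfile(
            sample_id=f"T0RD{day0:02d}",
            tank=0,
            compartment="root",
            day=day0,
            abundances=dict(zip(genera, draw.tolist())),
        )
    )
    for tank in design.tanks:
        for compartment in design.compartments:
            for day in design.sampling_days:
                if (tank, compartment, day) in design.missing_samples:
                    continue
                if compartment == "root" and day == day0:
                    continue
                mean = _genus_targets(design, genera, tank, compartment, day)
                mean = np.clip(mean, 1e-4, None)
                mean /= mean.sum()
                draw = rng.dirichlet(mean * design.dirichlet_concentration)
                draw /= draw.sum()
                sid = f"T{tank}{compartment[0].upper()}D{day:02d}"
                profiles.append(
                    CommunityProfile(
                        sample_id=sid,
                        tank=tank,
                        compartment=compartment,
                        day=day,
                        abundances=dict(zip(genera, draw.tolist())),
                    )
                )
    return profiles


def profiles_to_frame(profiles: Iterable[CommunityProfile]) -> pd.DataFrame:
    """Truth table: one row per sample, genus columns plus metadata columns."""
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id, "tank": p.tank,
               "compartment": p.compartment, "day": p.day}
        row.update(p.abundances)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(
    profile: CommunityProfile,
    db: ReferenceDB,
    n_reads: int,
    error_model: ErrorModel | None = None,
    seed: int = 0,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate noisy long reads from a community profile.

    Source references are drawn multinomially, taxon-proportionally (uniform
    across references within a genus). Per-base substitutions and indels are
    applied at the model rates and predicted qualities drawn from the model's
    mixture. Returns the reads plus a truth table (read_id, ref_id, genus).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not profile.abundances or sum(profile.abundances.values()) == 0:
        raise ValueError("empty community profile")
    em = error_model if error_model is not None else ErrorModel()
    rng = np.random.default_rng(seed)

    ref_ids: list[str] = []
    probs: list[float] = []
    for genus, frac in profile.abundances.items():
        members = db.genera.get(genus, ())
        if not members:
            continue
        for r in members:
            ref_ids.append(r)
            probs.append(frac / len(members))
    p = np.array(probs)
    p /= p.sum()
    counts = rng.multinomial(n_reads, p)

    ref_arrays = {r: _seq_to_array(db.sequences[r]) for r in ref_ids}
    reads: list[ReadRecord] = []
    truth_rows: list[tuple[str, str, str]] = []
    i = 0
    for r, c in zip(ref_ids, counts):
        genus = db.genus_of(r) or "unclassified"
        src = ref_arrays[r]
        for _ in range(c):
            read_id = f"{profile.sample_id}_r{i:06d}"
            seq, qual = _noisy_copy(src, em, rng)
            reads.append(ReadRecord(read_id, seq, qual))
            truth_rows.append((read_id, r, genus))
            i += 1
    order = rng.permutation(len(reads))
    reads = [reads[j] for j in order]
    truth = pd.DataFrame(
        [truth_rows[j] for j in order], columns=["read_id", "ref_id", "genus"]
    ).set_index("read_id")
    return reads, truth


def _noisy_copy(
    src: np.ndarray, em: ErrorModel, rng: np.random.Generator
) -> tuple[str, np.ndarray]:
    """Apply deletion/substitution/insertion noise to one template."""
    L = src.size
    if em.total_error > 0:
        keep = rng.random(L) >= em.deletion
        ins = rng.random(L) < em.insertion
        counts = keep.astype(np.int64) + ins.astype(np.int64)
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        total = int(counts.sum())
        out = np.empty(total, dtype=np.uint8)
        kept = src[keep]
        if kept.size:
            sub = rng.random(kept.size) < em.substitution
            if sub.any():
                kept = kept.copy()
                idx = np.searchsorted(_BASES, kept[sub])
                kept[sub] = _BASES[(idx + rng.integers(1, 4, size=int(sub.sum()))) % 4]
        out[starts[keep]] = kept
        if ins.any():
            ins_pos = starts[ins] + keep[ins].astype(np.int64)
            out[ins_pos] = _BASES[rng.integers(0, 4, size=int(ins.sum()))]
    else:
        out = src.copy()
        total = L
    if em.n_rate > 0 and total:
        n_mask = rng.random(total) < em.n_rate
        if n_mask.any():
            out[n_mask] = ord("N")
    # predicted qualities: mixture of decent reads and a low-quality tail
    mean_q = em.q_bad if rng.random() < em.bad_read_fraction else em.q_good
    qual = np.clip(np.rint(rng.normal(mean_q, em.q_sd, size=total)), 2, 41).astype(np.int64)
    return _array_to_seq(out), qual


# ---------------------------------------------------------------------------
# k-mer alignment scorer (desk-scale stand-in for a long-read aligner;
# real PAF input remains the production path)

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all valid k-mers (windows containing N are dropped)."""
    coded = _CODE[arr]
    if coded.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(coded, k)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1)
    return (win[valid] * powers).sum(axis=1)


def score_alignments(
    reads: Sequence[ReadRecord],
    db: ReferenceDB,
    k: int = 9,
    max_candidates: int = 100,
    min_score: float = 0.10,
    chunk_size: int = 2000,
) -> list[AlignmentRecord]:
    """Score reads against all references by shared-k-mer fraction.

    For each read the fraction of its k-mers present in each reference is
    computed; the top ``max_candidates`` references with score >= ``min_score``
    are emitted as alignments with ``n_matches / block_len`` equal to the
    score. Reads shorter than ``k`` are skipped with a logged warning.
    Deterministic given inputs.

    The default floor of 0.10 shared k-mers corresponds to roughly 77%
    sequence identity at k=9 — about the weakest hit a long-read aligner
    would report. A lower floor admits cross-genus noise alignments whose
    flat scores let EM smear abundance toward dominant taxa.
    """
    if not 6 <= k <= 12:
        raise ValueError("k must be in 6-12")
    if max_candidates > 100:
        raise ValueError("max_candidates must be <= 100")
    ref_ids = db.ref_ids
    m = len(ref_ids)
    presence = np.zeros((4 ** k, m), dtype=np.uint8)
    for j, r in enumerate(ref_ids):
        codes = _kmer_codes(_seq_to_array(db.sequences[r]), k)
        presence[codes, j] = 1

    out: list[AlignmentRecord] = []
    for start in range(0, len(reads), chunk_size):
        chunk = reads[start:start + chunk_size]
        code_list, bounds, kept_reads = [], [0], []
        for read in chunk:
            if len(read) < k:
                logger.warning("read %s shorter than k=%d; skipped", read.read_id, k)
                continue
            codes = _kmer_codes(_seq_to_array(read.sequence), k)
            if codes.size == 0:
                logger.warning("read %s has no valid k-mers; skipped", read.read_id)
                continue
            code_list.append(codes)
            bounds.append(bounds[-1] + codes.size)
            kept_reads.append(read)
        if not kept_reads:
            continue
        allcodes = np.concatenate(code_list)
        hits = presence[allcodes]  # (n_codes, m)
        sums = np.add.reduceat(hits.astype(np.int64), np.array(bounds[:-1]), axis=0)
        n_kmers = np.diff(bounds)
        scores = sums / n_kmers[:, None]
        for i, read in enumerate(kept_reads):
            srow = scores[i]
            cand = np.nonzero(srow >= min_score)[0]
            if cand.size == 0:
                continue
            top = cand[np.argsort(-srow[cand], kind="stable")][:max_candidates]
            best = float(srow[top[0]])
            if cand.size > 1:
                second = float(np.partition(srow[cand], -2)[-2])
                mapq = int(np.clip(60 * (best - second) / max(best, 1e-9), 0, 60))
            else:
                mapq = 60
            for j in top:
                out.append(
                    AlignmentRecord(
                        read_id=read.read_id,
                        ref_id=ref_ids[j],
                        read_len=len(read),
                        n_matches=int(sums[i, j]),
                        block_len=int(n_kmers[i]),
                        mapq=mapq,
                        strand="+",
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Water chemistry


def _gauss(t: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


def simulate_water_chemistry(
    design: StudyDesign,
    seed: int = 0,
    days: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-tank analyte time series with the nitrification cascade shape.

    Ammonia pulses early, nitrite follows, nitrate accumulates later; a tank
    flagged with a fish death receives a transient nitrate spike. Noise is
    multiplicative log-normal, drawn independently of the spike flag so that
    spiked and unspiked runs at the same seed differ only by the added spike
    mass. All concentrations are non-negative. Long format:
    (tank, day, analyte, value).
    """
    if days is None:
        days = list(range(0, 62, 2))
    t = np.asarray(days, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for tank in design.tanks:
        shapes = {
            "ammonia": 2.0 * _gauss(t, 10, 6),
            "nitrite": 1.5 * _gauss(t, 22, 8),
            "nitrate": 5.0 * _gauss(t, 32, 14),
            "pH": np.full_like(t, 7.2),
        }
        eit = design.inoculum_of(tank) == "EIT"
        noise = {a: rng.lognormal(0, 0.15, size=t.size) for a in shapes}
        for analyte, base in shapes.items():
            vals = base * noise[analyte]
            if eit and analyte in design.chemistry_shift:
                vals = vals + design.chemistry_shift[analyte]
            if analyte == "nitrate" and tank == design.nitrate_spike_tank:
                vals = vals + 8.0 * _gauss(t, design.death_day, 3.0)
            vals = np.clip(vals, 0, None)
            rows.extend(
                {"tank": tank, "day": int(d), "analyte": analyte, "value": float(v)}
                for d, v in zip(days, vals)
            )
    return pd.DataFrame(rows, columns=["tank", "day", "analyte", "value"])


# ---------------------------------------------------------------------------
# Plant phenotypes


def simulate_phenotypes(
    design: StudyDesign,
    profiles: Iterable[CommunityProfile],
    seed: int = 0,
    days: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-plant growth trajectories coupled to the root community.

    13 plants per tank are measured on a regular grid after transplanting.
    Growth increments shrink with the pathogen-like genus' final root
    abundance and grow with the diazotroph-like genus' abundance, scaled by
    the design effect sizes; heights are non-decreasing by construction.
    Columns: plant, tank, day, height_cm, leaves, root_length_cm.
    """
    if days is None:
        days = list(range(28, 62, 3))
    prof_list = list(profiles)
    root_final: dict[int, tuple[float, float]] = {}
    last_day = max(design.sampling_days)
    for p in prof_list:
        if p.compartment == "root" and p.day == last_day:
            root_final[p.tank] = (
                p.abundances.get(design.pathogen_genus, 0.0),
                p.abundances.get(design.diazotroph_genus, 0.0),
            )
    missing = [t for t in design.tanks if t not in root_final]
    if missing:
        raise ValueError(f"profiles do not cover the root compartment for tanks {missing}")
    rng = np.random.default_rng(seed)
    rows = []
    for tank in design.tanks:
        path_ab, diaz_ab = root_final[tank]
        factor = max(
            0.05,
            1.0
            - design.pathogen_growth_effect * path_ab
            + design.diazotroph_growth_effect * diaz_ab,
        )
        for plant in range(1, design.plants_per_tank + 1):
            height = float(rng.normal(4.0, 0.5))
            leaves = 3
            base_rate = max(0.1, rng.normal(0.9, 0.15))
            for day in days:
                inc = max(0.0, rng.normal(base_rate * factor, 0.15))
                height += inc
                leaves += rng.poisson(0.5 * factor)
                root_len = max(0.5, height * 0.8 * factor ** 0.5 + rng.normal(0, 0.5))
                rows.append(
                    {
                        "plant": f"T{tank}P{plant:02d}",
                        "tank": tank,
                        "day": int(day),
                        "height_cm": round(height, 2),
                        "leaves": int(leaves),
                        "root_length_cm": round(root_len, 2),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Validation tables with spurious taxa


def simulate_validation_tables(
    n_shared: int = 30,
    n_spurious: int = 50,
    spurious_mean: float = 20.0,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """Estimate/truth abundance pair emulating the cross-platform comparison.

    Shared taxa get log-normally perturbed copies of the truth abundances;
    the estimate additionally carries ``n_spurious`` off-target taxa with
    geometric (mean ``spurious_mean``) abundances absent from the truth —
    the regime in which a 300-count abundance cutoff removes nearly all of
    them. Returns (estimate, truth) as taxon-indexed count Series.
    """
    rng = np.random.default_rng(seed)
    truth_vals = np.exp(rng.uniform(np.log(50), np.log(50_000), size=n_shared))
    shared_ids = [f"Shared{i:03d}" for i in range(n_shared)]
    truth = pd.Series(np.round(truth_vals), index=shared_ids)
    est_shared = np.round(truth_vals * rng.lognormal(0, noise_sd, size=n_shared))
    spurious_ids = [f"Spurious{i:03d}" for i in range(n_spurious)]
    spurious_vals = rng.geometric(1.0 / spurious_mean, size=n_spurious).astype(float)
    estimate = pd.Series(
        np.concatenate([est_shared, spurious_vals]), index=shared_ids + spurious_ids
    )
    return estimate, truth
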