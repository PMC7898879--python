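"""Synthetic data generators with known ground truth.

Every downstream stage is exercised on data from this module: FASTQ-style
reads with injected QC violations, alignment hit tables over a toy
taxonomy with oracle-computable LCA outcomes, habitat-structured genus
count matrices with configurable bacterial:fungal ratios, and binary
occupancy matrices with known nestedness. Generators are deterministic:
the same seed and configuration yield bit-identical output.

Sequence content is random apart from the injected features; no realism
beyond quality scores is attempted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .qc import SequenceRead
from .taxonomy import TaxonomyTree
from .taxprofile import AlignmentHit

__all__ = [
    "SynthConfig",
    "gen_reads",
    "HitScenario",
    "gen_hit_table",
    "AbundanceTruth",
    "gen_abundance_matrix",
    "gen_nested_matrix",
]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# reads


def gen_reads(
    n: int,
    length: int = 100,
    quality_profile=35.0,
    p_ambiguous: float = 0.0,
    p_homopolymer: float = 0.0,
    seed: int = 0,
) -> tuple[list[SequenceRead], dict[str, Optional[str]]]:
    """Random reads, a known fraction carrying a constructed QC violation.

    Each read independently receives at most one violation: with
    probability ``p_ambiguous`` two N bases are inserted (breaking the
    "at most one ambiguous position" rule) and with probability
    ``p_homopolymer`` a 16-base homonucleotide run (breaking the 15-base
    run limit). Clean reads are rejection-sampled to contain neither, so
    with a high quality profile the constructed violation fully
    determines the QC outcome.

    Returns the reads plus a read-id -> violation map (``None`` = clean).
    """
    if n < 0 or length <= 0:
        raise ValueError("n must be >= 0 and length > 0")
    for name, p in (("p_ambiguous", p_ambiguous), ("p_homopolymer", p_homopolymer)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if p_ambiguous + p_homopolymer > 1:
        raise ValueError("violation probabilities must sum to at most 1")
    run = 16
    if p_homopolymer > 0 and length < run:
        raise ValueError(f"length must be >= {run} to inject homopolymer runs")
    rng = np.random.default_rng(seed)
    profile = np.broadcast_to(np.asarray(quality_profile, dtype=float), (length,))
    reads: list[SequenceRead] = []
    truth: dict[str, Optional[str]] = {}
    for i in range(n):
        u = rng.random()
        if u < p_ambiguous:
            violation = "ambiguity"
        elif u < p_ambiguous + p_homopolymer:
            violation = "homopolymer"
        else:
            violation = None
        while True:
            bases = rng.choice(_BASES, size=length)
            seq = "".join(bases)
            if violation is not None or _max_run(seq) <= 15:
                break
        if violation == "ambiguity":
            pos = rng.choice(length, size=2, replace=False)
            bases[pos] = "N"
        elif violation == "homopolymer":
            start = int(rng.integers(0, length - run + 1))
            bases[start:start + run] = rng.choice(_BASES)
        quals = np.clip(
            np.rint(rng.normal(profile, 1.5)), 10, 41
        ).astype(np.int64)
        rid = f"read_{i:05d}"
        reads.append(SequenceRead(rid, "".join(bases), quals))
        truth[rid] = violation
    return reads, truth


def _max_run(seq: str) -> int:
    best = cur = 1 if seq else 0
    for a, b in zip(seq, seq[1:]):
        cur = cur + 1 if a == b else 1
        best = max(best, cur)
    return best


# ---------------------------------------------------------------------------
# hit tables


@dataclass(frozen=True)
class HitScenario:
    """Recipe for one query's hit set.

    Hits target genera sampled from the subtree rooted at ``taxon`` (which
    must exist in the taxonomy), all with identities near ``identity``, so
    the gated-LCA outcome is computable by brute force over the tree.
    """

    read_id: str
    taxon: str
    n_hits: int = 3
    identity: float = 97.0
    identity_spread: float = 0.0
    evalue: Optional[float] = None


def gen_hit_table(
    scenarios: Sequence[HitScenario],
    tree: TaxonomyTree,
    seed: int = 0,
) -> list[AlignmentHit]:
    """Alignment hits realizing the given per-read scenarios."""
    rng = np.random.default_rng(seed)
    hits: list[AlignmentHit] = []
    for sc in scenarios:
        if sc.taxon not in tree:
            raise KeyError(f"scenario taxon {sc.taxon!r} not in taxonomy")
        genera = tree.genera(under=sc.taxon)
        if not genera:
            raise KeyError(f"taxon {sc.taxon!r} has no genus-level descendants")
        chosen = rng.choice(genera, size=sc.n_hits, replace=True)
        for genus in chosen:
            identity = float(
                np.clip(sc.identity + sc.identity_spread * rng.standard_normal(), 50, 100)
            )
            align_length = int(rng.integers(90, 151))
            evalue = (
                sc.evalue
                if sc.evalue is not None
                else float(10.0 ** -rng.uniform(5, 20))
            )
            hits.append(
                AlignmentHit(
                    query=sc.read_id,
                    target=f"ref|{genus}",
                    identity=round(identity, 2),
                    align_length=align_length,
                    evalue=evalue,
                    bitscore=round(2.0 * align_length * identity / 100.0, 1),
                    annotation=genus,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# abundance matrices


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the habitat-structured count generator.

    The bacterial:fungal split of each sample is binomial at
    r / (1 + r) for the habitat's configured ratio ``r``; within each
    kingdom, counts follow a Dirichlet-multinomial around the habitat's
    mean profile. ``habitat_effect`` scales the log-normal divergence of
    habitat (and habitat-group) mean profiles; 0 gives one shared profile
    and hence no recoverable habitat structure. ``dispersion`` is the
    inverse Dirichlet concentration (0 = plain multinomial).
    ``n_habitat_groups`` arranges habitats into blocks with shared
    group-level profiles (within-group divergence is 20% of the
    between-group divergence); ``n_exclusive_per_habitat`` appends
    bacterial genera whose abundance is confined to a single habitat, as
    ground truth for indicator analysis.
    """

    n_habitats: int = 3
    samples_per_habitat: int = 20
    n_bacterial_genera: int = 60
    n_fungal_genera: int = 40
    bf_ratio_per_habitat: tuple[float, ...] | float = (10.0, 220.0, 1305.0)
    habitat_effect: float = 1.0
    depth_range: tuple[int, int] = (100_000, 100_000)
    dispersion: float = 0.005
    n_habitat_groups: int = 1
    n_exclusive_per_habitat: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_habitats, self.samples_per_habitat,
               self.n_bacterial_genera, self.n_fungal_genera) < 1:
            raise ValueError("counts of habitats, samples and genera must be >= 1")
        lo, hi = self.depth_range
        if lo <= 0 or hi < lo:
            raise ValueError("depth_range must be a positive interval")
        ratios = self.ratios()
        if any(r <= 0 for r in ratios):
            raise ValueError("bf_ratio_per_habitat must be positive")
        if self.habitat_effect < 0 or self.dispersion < 0:
            raise ValueError("habitat_effect and dispersion must be non-negative")
        if not 1 <= self.n_habitat_groups <= self.n_habitats:
            raise ValueError("n_habitat_groups must be in [1, n_habitats]")

    def ratios(self) -> tuple[float, ...]:
        r = self.bf_ratio_per_habitat
        if np.isscalar(r):
            return (float(r),) * self.n_habitats
        if len(r) != self.n_habitats:
            raise ValueError("bf_ratio_per_habitat must match n_habitats")
        return tuple(float(v) for v in r)


@dataclass
class AbundanceTruth:
    """Sidecar ground truth emitted alongside a generated count matrix."""

    habitat_of: pd.Series  # sample -> habitat
    group_of: pd.Series  # habitat -> habitat group
    mean_profiles: pd.DataFrame  # habitat x genus expected relative abundance
    bf_ratio: pd.Series  # habitat -> configured B/F ratio
    exclusive_genera: dict[str, list[str]]  # habitat -> exclusive genus ids
    config: SynthConfig


def _softmax(logw: np.ndarray) -> np.ndarray:
    w = np.exp(logw - logw.max())
    return w / w.sum()


def gen_abundance_matrix(config: SynthConfig) -> tuple[CountMatrix, AbundanceTruth]:
    """Habitat-structured genus count matrix plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    habitats = [f"H{i + 1}" for i in range(config.n_habitats)]
    groups = {h: f"G{(i % config.n_habitat_groups) + 1}" for i, h in enumerate(habitats)}
    ratios = dict(zip(habitats, config.ratios()))

    n_excl = config.n_exclusive_per_habitat * config.n_habitats
    bact = [f"Bg{i + 1:03d}" for i in range(config.n_bacterial_genera)]
    excl = {
        h: [f"Bx{h}_{j + 1:02d}" for j in range(config.n_exclusive_per_habitat)]
        for h in habitats
    }
    excl_all = [g for h in habitats for g in excl[h]]
    fung = [f"Fg{i + 1:03d}" for i in range(config.n_fungal_genera)]

    base_b = rng.normal(0.0, 1.0, size=len(bact))
    base_f = rng.normal(0.0, 1.0, size=len(fung))
    group_ids = sorted(set(groups.values()))
    group_off_b = {g: rng.normal(0.0, config.habitat_effect, len(bact)) for g in group_ids}
    group_off_f = {g: rng.normal(0.0, config.habitat_effect, len(fung)) for g in group_ids}
    within = 0.2 if config.n_habitat_groups > 1 else 1.0

    profiles: dict[str, np.ndarray] = {}
    genera = bact + excl_all + fung
    for h in habitats:
        g = groups[h]
        log_b = base_b + group_off_b[g] + rng.normal(0.0, within * config.habitat_effect, len(bact))
        log_f = base_f + group_off_f[g] + rng.normal(0.0, within * config.habitat_effect, len(fung))
        p_b = _softmax(log_b)
        p_f = _softmax(log_f)
        # exclusive genera take a fixed 40% slice of this habitat's
        # bacterial mass, shared equally, and are absent elsewhere
        p_excl = np.zeros(n_excl)
        if config.n_exclusive_per_habitat:
            share = 0.4
            idx = habitats.index(h) * config.n_exclusive_per_habitat
            p_excl[idx:idx + config.n_exclusive_per_habitat] = (
                share / config.n_exclusive_per_habitat
            )
            p_b = p_b * (1 - share)
        r = ratios[h]
        p_bact_total = r / (1 + r)
        profiles[h] = np.concatenate(
            [p_b * p_bact_total, p_excl * p_bact_total, p_f * (1 - p_bact_total)]
        )

    lo, hi = config.depth_range
    rows, sample_ids, habitat_col, depth_col = [], [], [], []
    nb_all = len(bact) + n_excl
    for h in habitats:
        p = profiles[h]
        p_b = p[:nb_all] / p[:nb_all].sum()
        p_f = p[nb_all:] / p[nb_all:].sum()
        p_bact_total = p[:nb_all].sum()
        for s in range(config.samples_per_habitat):
            depth = int(rng.integers(lo, hi + 1))
            n_b = int(rng.binomial(depth, p_bact_total))
            n_f = depth - n_b
            row = np.concatenate(
                [_kingdom_counts(rng, n_b, p_b, config.dispersion),
                 _kingdom_counts(rng, n_f, p_f, config.dispersion)]
            )
            rows.append(row)
            sid = f"{h}_s{s + 1:02d}"
            sample_ids.append(sid)
            habitat_col.append(h)
            depth_col.append(depth)

    counts = pd.DataFrame(np.array(rows), index=sample_ids, columns=genera)
    sample_meta = pd.DataFrame(
        {"habitat": habitat_col, "total_reads": depth_col}, index=sample_ids
    )
    feature_meta = pd.DataFrame(
        {
            "kingdom": ["bacteria"] * nb_all + ["fungi"] * len(fung),
            "rank": "genus",
        },
        index=genera,
    )
    cm = CountMatrix(counts, sample_meta, feature_meta)
    truth = AbundanceTruth(
        habitat_of=sample_meta["habitat"],
        group_of=pd.Series(groups),
        mean_profiles=pd.DataFrame(profiles, index=genera).T,
        bf_ratio=pd.Series(ratios),
        exclusive_genera=excl,
        config=config,
    )
    return cm, truth


def _kingdom_counts(
    rng: np.random.Generator, n: int, p: np.ndarray, dispersion: float
) -> np.ndarray:
    if n == 0:
        return np.zeros(len(p), dtype=np.int64)
    if dispersion == 0:
        return rng.multinomial(n, p)
    alpha = p / dispersion
    return rng.multinomial(n, rng.dirichlet(alpha))


# ---------------------------------------------------------------------------
# nested occupancy matrices


def gen_nested_matrix(
    n_rows: int,
    n_cols: int,
    mode: str = "perfect",
    seed: int = 0,
    density: float = 0.5,
) -> np.ndarray:
    """Binary occupancy matrix with known nestedness structure.

    ``perfect``: a strictly nested staircase (row i has the first
    ``n_cols - i`` columns filled), with strictly decreasing row and
    column fills — NODF 100. ``equal_fill``: a permutation-style matrix
    with identical row fills and identical column fills — NODF 0, since
    no pair has decreasing fill. ``random``: independent Bernoulli fill
    at the given density.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if mode == "perfect":
        if n_rows > n_cols:
            raise ValueError("perfect staircase requires n_rows <= n_cols")
        m = np.zeros((n_rows, n_cols), dtype=int)
        for i in range(n_rows):
            m[i, : n_cols - i] = 1
        return m
    if mode == "equal_fill":
        m = np.zeros((n_rows, n_cols), dtype=int)
        for i in range(n_rows):
            m[i, i % n_cols] = 1
        return m
    if mode == "random":
        if not 0 <= density <= 1:
            raise ValueError("density must be in [0, 1]")
        rng = np.random.default_rng(seed)
        return (rng.random((n_rows, n_cols)) < density).astype(int)
    raise ValueError("mode must be 'perfect', 'equal_fill' or 'random'")
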