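"""Forward-in-time simulation of the pig population.

Two phases: a long random-mating historical phase of constant size that
builds linkage disequilibrium between markers and QTLs by drift (with a low
rate of recurrent symmetric mutation), and an 8-generation recent pedigree
with litters, sexes and 20% mortality by liability truncation.

Recombination follows the Haldane model: the number of crossovers on a
chromosome is Poisson with mean equal to the map length in Morgans and
crossover positions are uniform, i.e. no interference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BreedingConfig, GenomeConfig, HistoryConfig

__all__ = [
    "MarkerMap",
    "PopulationState",
    "InsufficientParentsError",
    "make_marker_map",
    "meiosis",
    "simulate_history",
    "found_base_population",
    "breed_generation",
]


class InsufficientParentsError(RuntimeError):
    """Raised when a generation lacks enough alive candidates of a sex."""


@dataclass
class MarkerMap:
    """Genetic map of markers and QTLs over all chromosomes.

    Loci are stored in (chromosome, position) order.  Markers are equally
    spaced along each 100 cM chromosome; QTL positions are uniform and
    distinct from marker positions.
    """

    chrom: np.ndarray  # int, 1-based chromosome
    pos_cm: np.ndarray  # float, centimorgans within chromosome
    is_qtl: np.ndarray  # bool
    ids: np.ndarray  # str locus ids

    def __post_init__(self) -> None:
        for c in np.unique(self.chrom):
            p = self.pos_cm[self.chrom == c]
            if not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on chr {c}")

    @property
    def n_loci(self) -> int:
        return self.chrom.size

    @property
    def marker_idx(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @property
    def qtl_idx(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    def chrom_slices(self) -> list:
        """Contiguous index slice per chromosome, in chromosome order."""
        slices = []
        for c in np.unique(self.chrom):
            w = np.flatnonzero(self.chrom == c)
            slices.append(slice(int(w[0]), int(w[-1]) + 1))
        return slices

    def chrom_lengths(self) -> np.ndarray:
        """Map length in cM per chromosome (max position, since maps start at 0)."""
        return np.array(
            [self.pos_cm[sl].max() - 0.0 for sl in self.chrom_slices()]
        )


def make_marker_map(genome: GenomeConfig, rng: np.random.Generator) -> MarkerMap:
    """Lay out markers (equally spaced) and QTLs (uniform) per chromosome."""
    chroms, pos, is_qtl, ids = [], [], [], []
    m, q = genome.markers_per_chr, genome.qtl_per_chr
    L = genome.chr_length_cm
    for c in range(1, genome.n_chr + 1):
        if m > 1:
            mpos = np.linspace(0.0, L, m, endpoint=False) + L / (2 * m)
        else:
            mpos = np.array([L / 2.0])
        qpos = rng.uniform(0.0, L, size=q)
        # QTL positions must not coincide with markers (or each other)
        while np.unique(np.concatenate([mpos, qpos])).size < m + q:
            qpos = rng.uniform(0.0, L, size=q)
        p = np.concatenate([mpos, qpos])
        flag = np.concatenate([np.zeros(m, bool), np.ones(q, bool)])
        order = np.argsort(p, kind="stable")
        chroms.append(np.full(m + q, c))
        pos.append(p[order])
        is_qtl.append(flag[order])
        ids.extend(
            f"{'q' if fl else 'm'}{c}_{i}" for i, fl in enumerate(flag[order])
        )
    return MarkerMap(
        chrom=np.concatenate(chroms),
        pos_cm=np.concatenate(pos),
        is_qtl=np.concatenate(is_qtl),
        ids=np.asarray(ids, dtype=object),
    )


def meiosis(
    rng: np.random.Generator,
    haplotypes: np.ndarray,
    mmap: MarkerMap,
    chrom_slices: list | None = None,
    chrom_lengths: np.ndarray | None = None,
) -> np.ndarray:
    """Produce one gamete from a parent's two haplotypes.

    Crossover count per chromosome ~ Poisson(length in Morgans); positions
    uniform (Haldane).  The starting haplotype is chosen at random per
    chromosome.  Returns an array of alleles over all loci.
    """
    if chrom_slices is None:
        chrom_slices = mmap.chrom_slices()
    if chrom_lengths is None:
        chrom_lengths = mmap.chrom_lengths()
    gamete = np.empty(mmap.n_loci, dtype=haplotypes.dtype)
    for sl, length in zip(chrom_slices, chrom_lengths):
        start = rng.integers(0, 2)
        n_cross = rng.poisson(length / 100.0) if length > 0 else 0
        if n_cross == 0:
            gamete[sl] = haplotypes[start, sl]
            continue
        cuts = np.sort(rng.uniform(0.0, length, size=n_cross))
        seg = np.searchsorted(cuts, mmap.pos_cm[sl])
        src = (start + seg) % 2
        block = haplotypes[:, sl]
        gamete[sl] = block[src, np.arange(src.size)]
    return gamete


def _mutate(rng: np.random.Generator, gamete: np.ndarray, rate: float) -> None:
    if rate <= 0:
        return
    hits = rng.random(gamete.size) < rate
    if hits.any():
        gamete[hits] ^= 1


def simulate_history(
    mmap: MarkerMap, cfg: HistoryConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Run the historical random-mating phase.

    Returns ``(haplotypes, sexes, summary)`` for the final historical
    generation; haplotypes have shape (N, 2, n_loci) with alleles in {0,1},
    sexes are 'M'/'F'.  The summary counts segregating markers and QTLs
    (minor allele count >= 1, i.e. both alleles present).
    """
    n_m, n_f = cfg.n_founder_males, cfg.n_founder_females
    n = n_m + n_f
    if n_m < 1 or n_f < 1:
        raise ValueError("need at least one founder of each sex")
    haps = (
        rng.random((n, 2, mmap.n_loci)) < cfg.founder_freq
    ).astype(np.uint8)
    sexes = np.array(["M"] * n_m + ["F"] * n_f)
    slices = mmap.chrom_slices()
    lengths = mmap.chrom_lengths()
    male_rows = np.arange(n_m)
    female_rows = np.arange(n_m, n)
    for _ in range(cfg.n_generations):
        new = np.empty_like(haps)
        sires = rng.choice(male_rows, size=n)
        dams = rng.choice(female_rows, size=n)
        for i in range(n):
            pat = meiosis(rng, haps[sires[i]], mmap, slices, lengths)
            mat = meiosis(rng, haps[dams[i]], mmap, slices, lengths)
            _mutate(rng, pat, cfg.mutation_rate)
            _mutate(rng, mat, cfg.mutation_rate)
            new[i, 0] = pat
            new[i, 1] = mat
        haps = new
    dosage = haps.sum(axis=1)
    seg = (dosage.sum(axis=0) > 0) & (dosage.sum(axis=0) < 2 * n)
    summary = {
        "n_segregating_markers": int(seg[mmap.marker_idx].sum()),
        "n_segregating_qtl": int(seg[mmap.qtl_idx].sum()),
        "n_markers": int(mmap.marker_idx.size),
        "n_qtl": int(mmap.qtl_idx.size),
    }
    if summary["n_segregating_markers"] == 0 and summary["n_segregating_qtl"] == 0:
        summary["all_fixed"] = True
    return haps, sexes, summary


@dataclass
class PopulationState:
    """Pedigree plus phased haplotypes for all individuals.

    IDs are sequential 1-based integers; row ``id - 1`` of ``haplotypes``
    belongs to individual ``id``.  Founders (generation 0) have sire = dam
    = 0.  ``litter`` is 0 for base animals.
    """

    mmap: MarkerMap
    pedigree: pd.DataFrame  # id, sire, dam, sex, generation, litter, alive
    haplotypes: np.ndarray  # (n, 2, n_loci) uint8
    _chrom_slices: list = field(default_factory=list, repr=False)
    _chrom_lengths: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self._chrom_slices:
            self._chrom_slices = self.mmap.chrom_slices()
        if self._chrom_lengths is None:
            self._chrom_lengths = self.mmap.chrom_lengths()

    @property
    def n(self) -> int:
        return len(self.pedigree)

    def rows(self, ids: np.ndarray) -> np.ndarray:
        return np.asarray(ids, dtype=int) - 1

    def dosages(self, ids: np.ndarray, loci_idx: np.ndarray) -> np.ndarray:
        """Allele dosage (0/1/2) matrix for ``ids`` at ``loci_idx``."""
        block = self.haplotypes[np.ix_(self.rows(ids), [0, 1], loci_idx)]
        return block.sum(axis=1).astype(np.float64)

    def ids_of_generation(self, gen: int) -> np.ndarray:
        return self.pedigree.loc[
            self.pedigree["generation"] == gen, "id"
        ].to_numpy()


def found_base_population(
    haps: np.ndarray,
    sexes: np.ndarray,
    mmap: MarkerMap,
    cfg: BreedingConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """Create generation 0 from the last historical generation.

    Randomly selects ``base_boars`` males; selects ``base_sows`` females
    (all of them when the historical population has exactly that many).
    """
    male_rows = np.flatnonzero(sexes == "M")
    female_rows = np.flatnonzero(sexes == "F")
    if male_rows.size < cfg.base_boars:
        raise InsufficientParentsError(
            f"need {cfg.base_boars} males, history has {male_rows.size}"
        )
    if female_rows.size < cfg.base_sows:
        raise InsufficientParentsError(
            f"need {cfg.base_sows} females, history has {female_rows.size}"
        )
    boars = np.sort(rng.choice(male_rows, size=cfg.base_boars, replace=False))
    sows = np.sort(rng.choice(female_rows, size=cfg.base_sows, replace=False))
    chosen = np.concatenate([boars, sows])
    n = chosen.size
    ped = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sire": 0,
            "dam": 0,
            "sex": ["M"] * cfg.base_boars + ["F"] * cfg.base_sows,
            "generation": 0,
            "litter": 0,
            "alive": 1,
        }
    )
    return PopulationState(
        mmap=mmap, pedigree=ped, haplotypes=haps[chosen].copy()
    )


def breed_generation(
    state: PopulationState, cfg: BreedingConfig, rng: np.random.Generator
) -> np.ndarray:
    """Append one generation of litters; returns the new individuals' ids.

    Sires and dams are sampled at random from the alive animals of the
    newest generation; each sire is mated to ``dams_per_sire`` dams and each
    dam produces one litter.  Litter sizes follow the configured law and
    piglet sexes are i.i.d. 1:1.  Offspring haplotypes are produced by
    meiosis (no mutation in the recent pedigree).  New animals start with
    ``alive = 1``; survival is assigned afterwards by liability truncation.
    """
    ped = state.pedigree
    gen = int(ped["generation"].max())
    prev = ped[ped["generation"] == gen]
    males = prev.loc[(prev["sex"] == "M") & (prev["alive"] == 1), "id"].to_numpy()
    females = prev.loc[(prev["sex"] == "F") & (prev["alive"] == 1), "id"].to_numpy()
    if males.size < cfg.n_sires:
        raise InsufficientParentsError(
            f"generation {gen}: {males.size} alive males < {cfg.n_sires} sires"
        )
    n_dams = cfg.n_dams
    if females.size < n_dams:
        if gen == 0:
            n_dams = females.size  # base population may be smaller by design
        else:
            raise InsufficientParentsError(
                f"generation {gen}: {females.size} alive females < {cfg.n_dams} dams"
            )
    sires = rng.choice(males, size=cfg.n_sires, replace=False)
    dams = rng.choice(females, size=n_dams, replace=False)
    dams = rng.permutation(dams)
    # round-robin assignment: dam j -> sire j // dams_per_sire (spills over
    # evenly when the base generation provides fewer dams than the design)
    sire_of_dam = sires[(np.arange(n_dams) * cfg.n_sires) // n_dams]
    litter_sizes = rng.choice(
        cfg.litter_sizes, size=n_dams, p=cfg.litter_probs
    )
    n_off = int(litter_sizes.sum())
    next_id = int(ped["id"].max()) + 1
    max_litter = int(ped["litter"].max())
    off_sire = np.repeat(sire_of_dam, litter_sizes)
    off_dam = np.repeat(dams, litter_sizes)
    off_litter = np.repeat(
        np.arange(max_litter + 1, max_litter + 1 + n_dams), litter_sizes
    )
    off_sex = np.where(rng.random(n_off) < 0.5, "M", "F")
    new_ped = pd.DataFrame(
        {
            "id": np.arange(next_id, next_id + n_off),
            "sire": off_sire,
            "dam": off_dam,
            "sex": off_sex,
            "generation": gen + 1,
            "litter": off_litter,
            "alive": 1,
        }
    )
    new_haps = np.empty((n_off, 2, state.mmap.n_loci), dtype=np.uint8)
    sire_rows = state.rows(off_sire)
    dam_rows = state.rows(off_dam)
    for k in range(n_off):
        new_haps[k, 0] = meiosis(
            rng, state.haplotypes[sire_rows[k]], state.mmap,
            state._chrom_slices, state._chrom_lengths,
        )
        new_haps[k, 1] = meiosis(
            rng, state.haplotypes[dam_rows[k]], state.mmap,
            state._chrom_slices, state._chrom_lengths,
        )
    state.pedigree = pd.concat([ped, new_ped], ignore_index=True)
    state.haplotypes = np.concatenate([state.haplotypes, new_haps], axis=0)
    return new_ped["id"].to_numpy()
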