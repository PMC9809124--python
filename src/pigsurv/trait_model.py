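"""QTL effects, true breeding values, liability and binary survival.

The phenotypic liability of piglet i is

    liability_i = a_i + m_dam(i) + l_litter(i) + e_i

where a is the piglet's own (direct) true breeding value, m the dam's
maternal true breeding value, l a common litter effect and e an independent
residual.  Survival is scored 1 for the top 80% of liabilities within each
generation cohort (20% mortality by truncation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import TraitArchitecture

__all__ = [
    "QtlEffectSet",
    "sample_qtl_effects",
    "calibrate_effects",
    "compute_tbv",
    "simulate_liability",
    "threshold_survival",
]


@dataclass
class QtlEffectSet:
    """Per-QTL (direct, maternal) allele substitution effects.

    ``scale_a``/``scale_m`` and ``center_a``/``center_m`` are post-hoc
    constants fixed on the scaling cohort (the base population) so that the
    realised variances of the direct and maternal TBVs equal the designed
    liability-scale variances exactly in that cohort, with cohort mean 0.
    """

    direct: np.ndarray
    maternal: np.ndarray
    scale_a: float = 1.0
    scale_m: float = 1.0
    center_a: float = 0.0
    center_m: float = 0.0
    calibrated: bool = False


def sample_qtl_effects(
    n_qtl: int, arch: TraitArchitecture, rng: np.random.Generator
) -> QtlEffectSet:
    """Draw correlated (direct, maternal) effect pairs for each QTL.

    Pairs come from a standard bivariate normal with correlation ``r_am``;
    the absolute scale is irrelevant because TBVs are rescaled on the base
    cohort afterwards (`calibrate_effects`).
    """
    if n_qtl < 2:
        raise ValueError("need at least 2 QTLs")
    r = arch.r_am
    alpha = rng.standard_normal(n_qtl)
    eps = rng.standard_normal(n_qtl)
    gamma = r * alpha + np.sqrt(max(0.0, 1.0 - r * r)) * eps
    return QtlEffectSet(direct=alpha, maternal=gamma)


def calibrate_effects(
    effects: QtlEffectSet,
    base_qtl_dosages: np.ndarray,
    arch: TraitArchitecture,
) -> QtlEffectSet:
    """Fix scaling constants on the scaling cohort (base population).

    After calibration the population variance (ddof=0) of the direct and
    maternal TBVs over the cohort equals ``var_direct``/``var_maternal``
    exactly, and both have cohort mean zero.
    """
    raw_a = base_qtl_dosages @ effects.direct
    raw_m = base_qtl_dosages @ effects.maternal
    sd_a = raw_a.std()
    sd_m = raw_m.std()
    if sd_a == 0 or sd_m == 0:
        raise ValueError("raw TBV variance is zero in the scaling cohort")
    effects.scale_a = np.sqrt(arch.var_direct) / sd_a
    effects.scale_m = np.sqrt(arch.var_maternal) / sd_m
    effects.center_a = raw_a.mean()
    effects.center_m = raw_m.mean()
    effects.calibrated = True
    return effects


def compute_tbv(
    qtl_dosages: np.ndarray, effects: QtlEffectSet
) -> tuple[np.ndarray, np.ndarray]:
    """True breeding values: dosage-weighted sums of QTL effects.

    a_i = scale_a * (sum_q dosage_iq * alpha_q - center_a); m analogous.
    Before calibration the raw (unscaled, uncentered) sums are returned.
    """
    if qtl_dosages.shape[1] != effects.direct.size:
        raise ValueError("dosage matrix does not match number of QTL effects")
    a = effects.scale_a * (qtl_dosages @ effects.direct - effects.center_a)
    m = effects.scale_m * (qtl_dosages @ effects.maternal - effects.center_m)
    return a, m


def simulate_liability(
    ped: pd.DataFrame,
    tbv_a: pd.Series,
    tbv_m: pd.Series,
    arch: TraitArchitecture,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Liabilities for the individuals in ``ped`` (one generation cohort).

    Every individual must have a known dam (maternal TBV) and a litter id;
    the litter effect is drawn once per litter, the residual per individual.
    """
    if (ped["dam"] == 0).any():
        raise ValueError("phenotyped individuals must have a known dam")
    litters, litter_codes = np.unique(ped["litter"].to_numpy(), return_inverse=True)
    l_eff = rng.normal(0.0, np.sqrt(arch.var_litter), size=litters.size)
    resid = rng.normal(0.0, np.sqrt(arch.var_residual), size=len(ped))
    a = tbv_a.loc[ped["id"]].to_numpy()
    m_dam = tbv_m.loc[ped["dam"]].to_numpy()
    liab = a + m_dam + l_eff[litter_codes] + resid
    return pd.DataFrame(
        {
            "id": ped["id"].to_numpy(),
            "generation": ped["generation"].to_numpy(),
            "litter": ped["litter"].to_numpy(),
            "liability": liab,
            "litter_effect": l_eff[litter_codes],
            "residual": resid,
            "tbv_a": a,
            "tbv_m": tbv_m.loc[ped["id"]].to_numpy(),
        }
    )


def threshold_survival(
    liabilities: np.ndarray, ids: np.ndarray, mortality: float = 0.20
) -> np.ndarray:
    """Binary survival by rank truncation within a cohort.

    Exactly round(mortality * n) individuals with the lowest liabilities are
    scored 0; ties are broken deterministically by (liability, id).
    """
    liabilities = np.asarray(liabilities, dtype=float)
    ids = np.asarray(ids)
    n = liabilities.size
    if n < 5:
        raise ValueError("thresholding cohort must have at least 5 individuals")
    n_dead = int(round(mortality * n))
    order = np.lexsort((ids, liabilities))  # primary liability, then id
    y = np.ones(n, dtype=int)
    y[order[:n_dead]] = 0
    return y
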