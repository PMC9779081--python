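"""Synthetic blood-PK curves, uptake assays, and biodistribution snapshots.

The generators mirror the structure of the experiments that parameterize
the model: blood sampling over 0-48 h after a normalized 100-%ID bolus,
and the colorimetric iron-uptake assay with three doses (0.125, 0.25,
0.5 mg Fe/mL), timepoints 3/6/12/24 h and replicate counts 3/2/1/3.
Noise is a truncated Gaussian with a proportional (constant-CV) and an
additive component; the defaults (CV = 10%, no additive term) match the
magnitude of the reported rate-table uncertainties.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sixcomp import Trajectory
from .two_compartment import ConcentrationCurve, TwoCompartmentParams, xb_analytic
from .uptake import UptakeParams, xin_analytic

__all__ = [
    "NoiseModel",
    "AssayDesign",
    "gen_blood_pk",
    "gen_uptake_assay",
    "gen_uptake_grid",
    "gen_bd_snapshot",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoiseModel:
    """Truncated-Gaussian measurement noise.

    value = truth * (1 + N(0, cv)) + N(0, additive_sd), clipped at zero.
    ``additive_sd`` is in the units of the generated quantity (%ID for
    blood curves, normalized amount for assays).
    """

    proportional_cv: float = 0.1
    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportional_cv < 0 or self.additive_sd < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, truth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        draws = truth * (1.0 + rng.normal(0.0, self.proportional_cv, truth.shape))
        if self.additive_sd > 0:
            draws = draws + rng.normal(0.0, self.additive_sd, truth.shape)
        n_trunc = int(np.sum(draws < 0))
        if n_trunc:
            logger.info("truncated %d negative noise draws to 0", n_trunc)
        return np.clip(draws, 0.0, None)


@dataclass(frozen=True)
class AssayDesign:
    """Dose/timepoint/replicate layout of an uptake experiment."""

    doses: tuple[float, ...] = (0.125, 0.25, 0.5)
    times: tuple[float, ...] = (3.0, 6.0, 12.0, 24.0)
    replicates: tuple[int, ...] = (3, 2, 1, 3)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.replicates):
            raise ValueError("times and replicates must have matching lengths")
        if any(r < 1 for r in self.replicates):
            raise ValueError("replicate counts must be >= 1")


def gen_blood_pk(
    params: TwoCompartmentParams,
    times: Sequence[float],
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 3,
) -> ConcentrationCurve:
    """Simulate a replicated blood concentration-time experiment.

    Returns per-timepoint replicate means with sample standard deviations
    (ddof=1; SDs are omitted when n_replicates == 1).
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0 or np.any(t < 0):
        raise ValueError("times must be nonempty and >= 0")
    truth = np.asarray(xb_analytic(params, t), dtype=float)
    rng = noise.rng()
    reps = noise.apply(np.tile(truth, (n_replicates, 1)), rng)
    means = reps.mean(axis=0)
    sds = reps.std(axis=0, ddof=1) if n_replicates > 1 else None
    return ConcentrationCurve(
        times=t,
        values=means,
        sds=sds,
        n_replicates=np.full(t.shape, n_replicates),
    )


def gen_uptake_assay(
    entry: UptakeParams,
    design: AssayDesign = AssayDesign(),
    noise: NoiseModel = NoiseModel(),
    config: str = "BNF-Plain",
    phenotype: str = "M0",
) -> pd.DataFrame:
    """Simulate one uptake time course per dose for a single rate entry.

    Amounts are normalized to the initial dose (X0 = 1), so the same
    (K_in, K_out) generates every dose and the dose column is a label of
    the emulated experiment rather than a model input.
    """
    rng = noise.rng()
    p = UptakeParams(entry.K_in, entry.K_out, X0=1.0)
    rows = []
    for dose in design.doses:
        for t, n_rep in zip(design.times, design.replicates):
            truth = float(xin_analytic(p, t))
            vals = noise.apply(np.full(n_rep, truth), rng)
            for r, v in enumerate(vals, start=1):
                rows.append(
                    {
                        "config": config,
                        "phenotype": phenotype,
                        "dose_mg_per_ml": dose,
                        "time_h": t,
                        "value": v,
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows)


def gen_uptake_grid(
    rates: pd.DataFrame,
    design: AssayDesign = AssayDesign(),
    noise: NoiseModel = NoiseModel(),
    dose: str = "average",
) -> pd.DataFrame:
    """Generate the full 3-configuration x 3-phenotype assay grid.

    Each (config, phenotype) series uses that entry's rates from
    ``rates`` (one seed-derived substream per series so datasets stay
    independent but reproducible).
    """
    from .uptake import NP_CONFIGS, PHENOTYPES, rate_entry

    frames = []
    for i, config in enumerate(NP_CONFIGS):
        for j, pheno in enumerate(PHENOTYPES):
            entry = rate_entry(rates, config, pheno, dose)
            sub_noise = NoiseModel(
                proportional_cv=noise.proportional_cv,
                additive_sd=noise.additive_sd,
                seed=noise.seed + 1000 * i + 100 * j,
            )
            frames.append(
                gen_uptake_assay(entry, design, sub_noise, config=config, phenotype=pheno)
            )
    return pd.concat(frames, ignore_index=True)


def gen_bd_snapshot(
    traj: Trajectory,
    tumor_mass_g: float = 0.225,
    organ_masses_g: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Endpoint biodistribution table in %ID and %ID per gram.

    Divides each compartment total at the final time by its tissue mass
    (default tumor mass 0.225 g: a 225 mm^3 tumor at density 1 g/cm^3).
    This is the inverse of the %ID/g -> %ID conversion used when
    importing literature biodistribution data.
    """
    masses = {"tumor": tumor_mass_g}
    if organ_masses_g:
        masses.update(organ_masses_g)
    totals = {
        "blood": float(traj.blood_total[-1]),
        "peripheral": float(traj.peripheral_total[-1]),
        "tumor": float(traj.tumor_total[-1]),
    }
    rows = []
    for comp, pct_id in totals.items():
        mass = masses.get(comp)
        if mass is not None and mass <= 0:
            raise ValueError(f"mass for {comp} must be positive")
        rows.append(
            {
                "compartment": comp,
                "time_h": float(traj.times[-1]),
                "pct_id": pct_id,
                "mass_g": mass,
                "pct_id_per_g": pct_id / mass if mass else np.nan,
            }
        )
    return pd.DataFrame(rows)
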