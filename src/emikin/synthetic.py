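"""Synthetic chromogenic-assay data at the designs of the calibration study.

No raw plate-reader data is deposited with the study, so calibration,
validation and comparison stages run on synthetic duplicate-well time
courses generated from the models at the published parameter estimates.
Noise is applied to the readout (what a plate reader measures), not to
internal states: multiplicative scatter with a small additive floor,
independently per replicate well.  The true experimental noise magnitude
is not reported; the defaults (3% CV, 0.5 nM floor, duplicate wells) are
declared in the generated metadata.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .io import SCHEMA, TimecourseData
from .network import ExperimentDesign, simulate, species_total
from .one_arm import OneArmVariant, build_one_arm
from .one_arm import make_design as one_arm_design
from .params import LipidConfig, RateParameters
from .two_arm import (
    DEFAULT_FX_TITRATION,
    DEFAULT_M_TITRATION,
    ChromogenicConfig,
    TernaryPathwayConfig,
    build_two_arm,
    chromophore_timecourse,
)
from .two_arm import make_design as two_arm_design


@dataclass(frozen=True)
class NoiseModel:
    """Plate-reader-like readout noise: value*(1+cv*z) + floor*z', clipped at 0."""

    cv: float = 0.03
    floor_nM: float = 0.5
    replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0 or self.floor_nM < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def design_library(lipid: LipidConfig | None = None) -> dict[str, list[ExperimentDesign]]:
    """The named design sets of the study, with the printed concentrations.

    * ``no_emicizumab_fx_titration`` — FX titration, 1 nM FIXa, 80 uM
      lipid, no antibody, 90 min chromogenic read (calibration step 1).
    * ``emicizumab_titration`` — 140 nM FX, 1 nM FIXa, 80 uM lipid,
      varied emicizumab, 30 min (calibration step 2).
    * ``one_arm_emicizumab_titration`` — TF:VIIa 0.5 nM, 140 nM FX, 80 uM
      lipid, emicizumab 0-50 uM, FXa readout (hypothesis discrimination).
    * ``validation_fx_titration`` — emicizumab fixed at 400 nM, FX varied
      (forward-prediction check).
    * ``no_lipid_control`` — 10 nM FIXa without lipid.
    """
    lipid = lipid or LipidConfig()
    chromo_S0 = ChromogenicConfig().S0_nM
    lib: dict[str, list[ExperimentDesign]] = {}
    lib["no_emicizumab_fx_titration"] = [
        two_arm_design(FX_nM=fx, FIXa_nM=1.0, M_nM=0.0, lipid_uM=80.0,
                       duration_s=5400.0, S0_nM=chromo_S0, readout="chromophore",
                       lipid=lipid, label=f"noM_FX{fx:g}")
        for fx in DEFAULT_FX_TITRATION
    ]
    lib["emicizumab_titration"] = [
        two_arm_design(FX_nM=140.0, FIXa_nM=1.0, M_nM=m, lipid_uM=80.0,
                       duration_s=1800.0, S0_nM=chromo_S0, readout="chromophore",
                       lipid=lipid, label=f"M{m:g}")
        for m in DEFAULT_M_TITRATION
    ]
    lib["one_arm_emicizumab_titration"] = [
        one_arm_design(FX_nM=140.0, M_nM=m, lipid_uM=80.0, TFVIIa_nM=0.5,
                       duration_s=1800.0, lipid=lipid, label=f"oneM{m:g}")
        for m in (0.0, 400.0, 3000.0, 10000.0, 50000.0)
    ]
    lib["validation_fx_titration"] = [
        two_arm_design(FX_nM=fx, FIXa_nM=1.0, M_nM=400.0, lipid_uM=80.0,
                       duration_s=1800.0, S0_nM=chromo_S0, readout="chromophore",
                       lipid=lipid, label=f"val_FX{fx:g}")
        for fx in DEFAULT_FX_TITRATION[:5]
    ]
    lib["no_lipid_control"] = [
        two_arm_design(FX_nM=140.0, FIXa_nM=10.0, M_nM=400.0, lipid_uM=0.0,
                       duration_s=5400.0, S0_nM=chromo_S0, readout="chromophore",
                       lipid=lipid, label="no_lipid_IXa10")
    ]
    return lib


def _readout_series(traj, readout: str) -> np.ndarray:
    if readout == "chromophore":
        return chromophore_timecourse(traj)
    if readout == "total_FXa":
        return species_total(traj, "FXa")
    raise ValueError(f"unknown readout {readout!r}")


def _network_for(design: ExperimentDesign, params: RateParameters,
                 pathways: TernaryPathwayConfig | None, cache: dict):
    one_arm = design.meta.get("TFVIIa_nM", 0.0) > 0
    chromo = design.readout == "chromophore"
    key = (one_arm, chromo)
    if key not in cache:
        if one_arm:
            cache[key] = build_one_arm(params=params)
        else:
            cfg = ChromogenicConfig() if chromo else None
            cache[key] = build_two_arm(pathways, chromo=cfg, params=params)
    return cache[key]


def generate(
    designs: list[ExperimentDesign],
    theta_true: RateParameters,
    noise: NoiseModel | None = None,
    pathways: TernaryPathwayConfig | None = None,
    variant: OneArmVariant | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> TimecourseData:
    """Simulate each design at ``theta_true`` and add replicate-wise noise.

    One-arm designs (TF:VIIa present) are run with ``variant`` applied
    (default: the partial-inhibition variant at the theta values).
    Records theta, noise settings and seed in the metadata sidecar.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    cache: dict = {}
    rows = []
    failures = []
    for design in designs:
        net = _network_for(design, theta_true, pathways, cache)
        run_params = theta_true
        if design.meta.get("TFVIIa_nM", 0.0) > 0:
            var = variant or OneArmVariant.D(theta_true["alpha"], theta_true["beta"])
            run_params = var.apply(theta_true)
        try:
            traj = simulate(net, run_params, design, rtol=rtol, atol=atol)
        except Exception as exc:  # surface per design, let others proceed
            failures.append((design.label, str(exc)))
            continue
        clean = _readout_series(traj, design.readout)
        for rep in range(1, noise.replicates + 1):
            z = rng.standard_normal(clean.shape)
            z2 = rng.standard_normal(clean.shape)
            noisy = np.clip(clean * (1.0 + noise.cv * z) + noise.floor_nM * z2,
                            0.0, None)
            for t, v in zip(traj.times, noisy):
                rows.append(
                    (design.label, design.meta["M_nM"], design.meta["FX_nM"],
                     design.meta["FIXa_nM"], design.meta["TFVIIa_nM"],
                     design.meta["lipid_uM"], rep, t, design.readout, v)
                )
    if failures and not rows:
        raise RuntimeError(f"all designs failed: {failures}")
    frame = pd.DataFrame(rows, columns=SCHEMA)
    meta = {
        "theta_true": dict(theta_true),
        "noise": asdict(noise),
        "seed": noise.seed,
        "failures": failures,
        "note": "synthetic data; experimental noise magnitude is a declared placeholder",
    }
    return TimecourseData(frame=frame, meta=meta)
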