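"""FIXa-emicizumab-FX model with lipid-surface ternary-complex formation.

TF:VIIa is absent; FIXa is the enzyme.  FX activation proceeds through
two catalytic routes:

* the direct lipid-bound FIXa:FX complex (slow, ``kcat_noM``);
* the ternary complex FIXa:M:FX bridged by emicizumab on the surface
  (fast, ``kcat_ternary``), assembled through up to three pathways:

  1. M binds a lipid-bound protein (FX/FXa or FIXa) and the complex then
     binds the other lipid-bound partner;
  2. M binds its partner in solution, the complex binds lipid (association
     scaled by ``alpha``) and then the other lipid-bound partner;
  3. M binds the preformed lipid-bound FIXa:FX complex directly.

The ternary complex dissociates when emicizumab releases either arm;
pathway flags therefore gate association channels only, dissociations are
always present.  Upon activation the FX in the ternary becomes FXa in
place and emicizumab releases it at ``gamma_MXa`` times the M:FX off-rate,
freeing the enzyme arm for another round.

An optional solution-phase extension adds ternary assembly and FX
activation in solution at the individual solution binding rates and the
same catalytic rate as on the surface; it is off by default because it is
negligible at the lipid concentration of the calibration assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import (
    LIPID_MINUS,
    ExperimentDesign,
    ReactionNetwork,
    Species,
    Trajectory,
    build_network,
    reaction,
    simulate,
)
from .params import LipidConfig, RateParameters

#: default emicizumab-free FX titration (nM) emulating the no-antibody assay
DEFAULT_FX_TITRATION = (35.0, 70.0, 140.0, 280.0, 560.0, 1120.0)
#: default emicizumab titration (nM) emulating the varied-antibody assay
DEFAULT_M_TITRATION = (50.0, 150.0, 400.0, 1200.0, 3600.0)


@dataclass(frozen=True)
class TernaryPathwayConfig:
    """Which ternary-assembly association channels are enabled."""

    path1_surface_assembly: bool = True
    path2_solution_then_lipid: bool = True
    path3_bind_preformed_IXaX: bool = True
    solution_phase_activation: bool = False

    def __post_init__(self):
        if not (self.path1_surface_assembly or self.path2_solution_then_lipid
                or self.path3_bind_preformed_IXaX):
            raise ValueError("at least one ternary pathway must be enabled")


@dataclass(frozen=True)
class ChromogenicConfig:
    """Chromogenic-substrate readout: S is cleaved to chromophore C by FXa.

    ``cleaving_species`` lists the FXa-containing species with a free
    active site that process substrate; each gets a Michaelis complex
    ``<species>:S``.  Rates come from the ``kSon``/``kSoff``/``kScat``
    parameter keys.
    """

    S0_nM: float = 3.0e5  # 300 uM substrate
    cleaving_species: tuple[str, ...] = ("Xa", "M:Xa", "Xab", "M:Xab")

    def __post_init__(self):
        if self.S0_nM <= 0:
            raise ValueError("S0 must be > 0 for chromophore readouts")


def _sp(name, compartment, composition, sites=0):
    return Species(name, compartment, composition, sites)


def build_two_arm(
    pathways: TernaryPathwayConfig | None = None,
    chromo: ChromogenicConfig | None = None,
    params: RateParameters | None = None,
) -> ReactionNetwork:
    """Build the two-arm reaction network (see module docstring)."""
    pathways = pathways or TernaryPathwayConfig()
    L = LIPID_MINUS  # single, TF-free surface pool

    species = [
        _sp("X", "solution", {"FX": 1}),
        _sp("Xa", "solution", {"FXa": 1}),
        _sp("IXa", "solution", {"FIXa": 1}),
        _sp("M", "solution", {"M": 1}),
        _sp("M:X", "solution", {"M": 1, "FX": 1}),
        _sp("M:Xa", "solution", {"M": 1, "FXa": 1}),
        _sp("IXa:M", "solution", {"FIXa": 1, "M": 1}),
        _sp("L", L, {}, sites=1),
        _sp("Xb", L, {"FX": 1}, sites=1),
        _sp("Xab", L, {"FXa": 1}, sites=1),
        _sp("IXab", L, {"FIXa": 1}, sites=1),
        _sp("M:Xb", L, {"M": 1, "FX": 1}, sites=1),
        _sp("M:Xab", L, {"M": 1, "FXa": 1}, sites=1),
        _sp("IXa:Mb", L, {"FIXa": 1, "M": 1}, sites=1),
        _sp("IXa:Xb", L, {"FIXa": 1, "FX": 1}, sites=2),
        _sp("IXa:M:Xb", L, {"FIXa": 1, "M": 1, "FX": 1}, sites=2),
        _sp("IXa:M:Xab", L, {"FIXa": 1, "M": 1, "FXa": 1}, sites=2),
    ]
    if pathways.solution_phase_activation:
        species += [
            _sp("IXa:M:X", "solution", {"FIXa": 1, "M": 1, "FX": 1}),
            _sp("IXa:M:Xa", "solution", {"FIXa": 1, "M": 1, "FXa": 1}),
        ]

    rx = [
        # lipid binding of free proteins
        reaction(["X", "L"], ["Xb"], "kXon", "association"),
        reaction(["Xb"], ["X", "L"], "kXoff", "dissociation"),
        reaction(["Xa", "L"], ["Xab"], "kXon", "association"),
        reaction(["Xab"], ["Xa", "L"], "kXoff", "dissociation"),
        reaction(["IXa", "L"], ["IXab"], "kIXon", "association"),
        reaction(["IXab"], ["IXa", "L"], "kIXoff", "dissociation"),
        # emicizumab in solution
        reaction(["M", "X"], ["M:X"], "kMX_on", "association"),
        reaction(["M:X"], ["M", "X"], "kMX_off", "dissociation"),
        reaction(["M", "Xa"], ["M:Xa"], "kMX_on", "association"),
        reaction(["M:Xa"], ["M", "Xa"], "kMX_off", "dissociation",
                 scale_keys=["gamma_MXa"]),
        reaction(["M", "IXa"], ["IXa:M"], "kMIX_on", "association"),
        reaction(["IXa:M"], ["M", "IXa"], "kMIX_off", "dissociation"),
        # direct lipid-bound FIXa:FX complex and slow turnover
        reaction(["IXab", "Xb"], ["IXa:Xb"], "kIXaX_on", "association"),
        reaction(["IXa:Xb"], ["IXab", "Xb"], "kIXaX_off", "dissociation"),
        reaction(["IXa:Xb"], ["IXab", "Xab"], "kcat_noM", "catalysis"),
        # dissociation channels of M-bearing surface species (always present)
        reaction(["M:Xb"], ["M", "Xb"], "kMX_off", "dissociation"),
        reaction(["M:Xab"], ["M", "Xab"], "kMX_off", "dissociation",
                 scale_keys=["gamma_MXa"]),
        reaction(["IXa:Mb"], ["M", "IXab"], "kMIX_off", "dissociation"),
        reaction(["M:Xb"], ["M:X", "L"], "kXoff", "dissociation"),
        reaction(["M:Xab"], ["M:Xa", "L"], "kXoff", "dissociation"),
        reaction(["IXa:Mb"], ["IXa:M", "L"], "kIXoff", "dissociation"),
        # ternary dissociation: emicizumab releases either arm
        reaction(["IXa:M:Xb"], ["IXab", "M:Xb"], "kMIX_off", "dissociation"),
        reaction(["IXa:M:Xb"], ["IXa:Mb", "Xb"], "kMX_off", "dissociation"),
        reaction(["IXa:M:Xab"], ["IXab", "M:Xab"], "kMIX_off", "dissociation"),
        reaction(["IXa:M:Xab"], ["IXa:Mb", "Xab"], "kMX_off", "dissociation",
                 scale_keys=["gamma_MXa"]),
        # activation inside the surface ternary: FX -> FXa in place
        reaction(["IXa:M:Xb"], ["IXa:M:Xab"], "kcat_ternary", "catalysis"),
    ]
    if pathways.path1_surface_assembly:
        rx += [
            reaction(["M", "Xb"], ["M:Xb"], "kMX_on", "association"),
            reaction(["M", "Xab"], ["M:Xab"], "kMX_on", "association"),
            reaction(["M", "IXab"], ["IXa:Mb"], "kMIX_on", "association"),
        ]
    if pathways.path2_solution_then_lipid:
        rx += [
            reaction(["M:X", "L"], ["M:Xb"], "kXon", "association",
                     scale_keys=["alpha"]),
            reaction(["M:Xa", "L"], ["M:Xab"], "kXon", "association",
                     scale_keys=["alpha"]),
            reaction(["IXa:M", "L"], ["IXa:Mb"], "kIXon", "association",
                     scale_keys=["alpha"]),
        ]
    if pathways.path1_surface_assembly or pathways.path2_solution_then_lipid:
        rx += [
            # surface ternary assembly from either surface intermediate
            reaction(["IXab", "M:Xb"], ["IXa:M:Xb"], "kTon_surf", "association"),
            reaction(["IXa:Mb", "Xb"], ["IXa:M:Xb"], "kIXaM_X_on", "association"),
            reaction(["IXab", "M:Xab"], ["IXa:M:Xab"], "kTon_surf", "association"),
            reaction(["IXa:Mb", "Xab"], ["IXa:M:Xab"], "kIXaM_X_on", "association"),
        ]
    if pathways.path3_bind_preformed_IXaX:
        rx += [
            reaction(["M", "IXa:Xb"], ["IXa:M:Xb"], "kMX_on", "association"),
        ]
    if pathways.solution_phase_activation:
        rx += [
            reaction(["IXa", "M:X"], ["IXa:M:X"], "kMIX_on", "association"),
            reaction(["IXa:M:X"], ["IXa", "M:X"], "kMIX_off", "dissociation"),
            reaction(["X", "IXa:M"], ["IXa:M:X"], "kMX_on", "association"),
            reaction(["IXa:M:X"], ["X", "IXa:M"], "kMX_off", "dissociation"),
            reaction(["IXa:M:X"], ["IXa:M:Xa"], "kcat_ternary", "catalysis"),
            reaction(["IXa:M:Xa"], ["IXa:M", "Xa"], "kMX_off", "dissociation",
                     scale_keys=["gamma_MXa"]),
            reaction(["IXa:M:Xa"], ["IXa", "M:Xa"], "kMIX_off", "dissociation"),
            reaction(["Xa", "IXa:M"], ["IXa:M:Xa"], "kMX_on", "association"),
            reaction(["IXa", "M:Xa"], ["IXa:M:Xa"], "kMIX_on", "association"),
        ]
    if chromo is not None:
        species += [
            _sp("S", "solution", {"S": 1}),
            _sp("C", "solution", {"C": 1}),
        ]
        base = {s.name: s for s in species}
        for z in chromo.cleaving_species:
            if z not in base:
                raise ValueError(f"cleaving species {z!r} not in network")
            sp = base[z]
            comp = dict(sp.composition)
            comp["S"] = comp.get("S", 0) + 1
            species.append(_sp(f"{z}:S", sp.compartment, comp, sites=sp.sites))
            rx += [
                reaction([z, "S"], [f"{z}:S"], "kSon", "association"),
                reaction([f"{z}:S"], [z, "S"], "kSoff", "dissociation"),
                reaction([f"{z}:S"], [z, "C"], "kScat", "catalysis"),
            ]

    net = build_network(species, rx, name="two_arm")
    if params is not None:
        missing = sorted(
            {r.rate_key for r in rx if r.rate_key not in params}
            | {k for r in rx for k in r.scale_keys if k not in params}
        )
        if missing:
            raise KeyError(f"missing rates for two-arm model: {missing}")
    return net


def make_design(
    FX_nM: float,
    FIXa_nM: float = 1.0,
    M_nM: float = 0.0,
    lipid_uM: float = 80.0,
    duration_s: float = 1800.0,
    dt_s: float = 60.0,
    S0_nM: float | None = None,
    readout: str = "total_FXa",
    lipid: LipidConfig | None = None,
    label: str = "",
) -> ExperimentDesign:
    """Assay design for the FIXa system (readout FXa or chromophore)."""
    lipid = lipid or LipidConfig()
    conc = {
        "X": FX_nM,
        "IXa": FIXa_nM,
        "M": M_nM,
        "L": lipid.sites_nM(lipid_uM),
    }
    if S0_nM:
        conc["S"] = S0_nM
    return ExperimentDesign(
        initial_concentrations={k: v for k, v in conc.items() if v > 0},
        duration=duration_s,
        sample_times=np.arange(0.0, duration_s + 1e-9, dt_s),
        readout=readout,
        label=label or f"two_arm_M{M_nM:g}_FX{FX_nM:g}",
        meta={
            "M_nM": M_nM, "FX_nM": FX_nM, "FIXa_nM": FIXa_nM,
            "TFVIIa_nM": 0.0, "lipid_uM": lipid_uM,
        },
    )


def chromophore_timecourse(trajectory: Trajectory) -> np.ndarray:
    """Released chromophore (nM); monotone non-decreasing, bounded by S0."""
    if "C" not in trajectory.network.index:
        raise KeyError("trajectory has no chromogenic readout (no substrate species)")
    return trajectory.series("C")


def ternary_partition(trajectory: Trajectory, t: float) -> tuple[float, float]:
    """(solution, lipid-bound) FIXa:M:FX ternary concentration (nM) at time t."""
    if t < trajectory.times[0] - 1e-9 or t > trajectory.times[-1] + 1e-9:
        raise ValueError(f"t = {t} s outside the trajectory range")
    state = trajectory.at_time(t)
    idx = trajectory.network.index
    sol = state[idx["IXa:M:X"]] if "IXa:M:X" in idx else 0.0
    lip = state[idx["IXa:M:Xb"]] if "IXa:M:Xb" in idx else 0.0
    return float(sol), float(lip)


def lipid_scan_ternary(
    lipid_grid_uM: np.ndarray,
    params: RateParameters,
    reduced_assoc: bool = False,
    FX_nM: float = 140.0,
    FIXa_nM: float = 1.0,
    M_nM: float = 400.0,
    t_s: float = 120.0,
    lipid: LipidConfig | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> pd.DataFrame:
    """Ternary-complex partition versus lipid with the solution-phase extension.

    With ``reduced_assoc`` the surface-assembly association rate is lowered
    to the solution-phase value (the emicizumab-FIXa on-rate), probing how
    much of the complex owes its existence to membrane colocalization.
    """
    lipid_grid_uM = np.asarray(lipid_grid_uM, dtype=float)
    if lipid_grid_uM.size == 0:
        raise ValueError("lipid grid is empty")
    pathways = TernaryPathwayConfig(solution_phase_activation=True)
    net = build_two_arm(pathways, params=params)
    run_params = params
    if reduced_assoc:
        run_params = params.with_updates(kTon_surf=params["kMIX_on"])
    rows = []
    for lip_uM in lipid_grid_uM:
        design = make_design(FX_nM=FX_nM, FIXa_nM=FIXa_nM, M_nM=M_nM,
                             lipid_uM=lip_uM, duration_s=max(t_s, 120.0),
                             dt_s=t_s / 4, lipid=lipid)
        traj = simulate(net, run_params, design, rtol=rtol, atol=atol)
        sol, surf = ternary_partition(traj, t_s)
        rows.append((lip_uM, sol, surf, sol + surf))
    return pd.DataFrame(
        rows,
        columns=["lipid_uM", "solution_ternary_nM", "lipid_ternary_nM",
                 "total_ternary_nM"],
    )
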