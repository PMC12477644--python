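"""TF:VIIa activation of FX on lipid vesicles with one-arm emicizumab binding.

Emicizumab (M) engages FX/FXa through its anti-FX arm only (no FIXa in
these assays).  Three non-exclusive mechanisms are represented:

1. M in solution binds lipid-bound FX/FXa directly (solution rates).
2. M binds solution FX/FXa and the M:X / M:Xa complex then binds the
   surface, with its association scaled by ``alpha``.
3. TF:VIIa binds (and activates) M-bound, lipid-bound FX with its
   association scaled by ``beta`` and an unchanged catalytic rate.

The competing hypotheses about the inhibitory mechanism are encoded as
variants pinning ``alpha``/``beta``:

=========  =====  =====  ==============================================
variant    alpha  beta   interpretation
=========  =====  =====  ==============================================
A          1      1      emicizumab changes no rate
B          0      1      emicizumab-bound FX/FXa cannot bind lipid
C          1      0      emicizumab-bound FX cannot bind TF:VIIa
D          free   free   partial inhibition of both (the retained model)
=========  =====  =====  ==============================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .network import (
    LIPID_MINUS,
    LIPID_PLUS,
    ExperimentDesign,
    ReactionNetwork,
    Species,
    Trajectory,
    build_network,
    reaction,
    simulate,
    species_total,
)
from .params import LipidConfig, RateParameters


@dataclass(frozen=True)
class OneArmVariant:
    """A hypothesis about how emicizumab perturbs FX handling (see module docs)."""

    label: str
    alpha: float
    beta: float

    def __post_init__(self):
        pinned = {"A_no_effect": (1.0, 1.0), "B_block_lipid": (0.0, 1.0),
                  "C_block_tfviia": (1.0, 0.0)}
        if self.label in pinned and (self.alpha, self.beta) != pinned[self.label]:
            raise ValueError(f"variant {self.label} pins alpha/beta to {pinned[self.label]}")
        if self.label == "D_scaled" and not (0 <= self.alpha <= 1 and 0 <= self.beta <= 1):
            raise ValueError("variant D requires alpha, beta in [0, 1]")

    @classmethod
    def A(cls):
        return cls("A_no_effect", 1.0, 1.0)

    @classmethod
    def B(cls):
        return cls("B_block_lipid", 0.0, 1.0)

    @classmethod
    def C(cls):
        return cls("C_block_tfviia", 1.0, 0.0)

    @classmethod
    def D(cls, alpha: float, beta: float):
        return cls("D_scaled", alpha, beta)

    def apply(self, params: RateParameters) -> RateParameters:
        return params.with_updates(alpha=self.alpha, beta=self.beta)


def _sp(name, compartment, composition, sites=0):
    return Species(name, compartment, composition, sites)


def build_one_arm(variant: OneArmVariant | None = None,
                  params: RateParameters | None = None) -> ReactionNetwork:
    """Build the one-arm reaction network.

    The network topology is the same for every variant; variants differ
    only in the values bound to ``alpha`` and ``beta`` at simulation time
    (use :meth:`OneArmVariant.apply`).  ``params`` is accepted to verify
    rate-key coverage eagerly when given.
    """
    species = [
        _sp("X", "solution", {"FX": 1}),
        _sp("Xa", "solution", {"FXa": 1}),
        _sp("M", "solution", {"M": 1}),
        _sp("M:X", "solution", {"M": 1, "FX": 1}),
        _sp("M:Xa", "solution", {"M": 1, "FXa": 1}),
        _sp("L+", LIPID_PLUS, {}, sites=1),
        _sp("L-", LIPID_MINUS, {}, sites=1),
        _sp("E", LIPID_PLUS, {"TFVIIa": 1}),
        _sp("E:Xb", LIPID_PLUS, {"TFVIIa": 1, "FX": 1}, sites=1),
        _sp("E:M:Xb", LIPID_PLUS, {"TFVIIa": 1, "M": 1, "FX": 1}, sites=1),
    ]
    for tag, comp in (("+", LIPID_PLUS), ("-", LIPID_MINUS)):
        species += [
            _sp(f"Xb{tag}", comp, {"FX": 1}, sites=1),
            _sp(f"Xab{tag}", comp, {"FXa": 1}, sites=1),
            _sp(f"M:Xb{tag}", comp, {"M": 1, "FX": 1}, sites=1),
            _sp(f"M:Xab{tag}", comp, {"M": 1, "FXa": 1}, sites=1),
        ]

    rx = []
    for tag in ("+", "-"):
        L = f"L{tag}"
        # FX/FXa lipid binding, identical rates on both pools
        rx += [
            reaction(["X", L], [f"Xb{tag}"], "kXon", "association"),
            reaction([f"Xb{tag}"], ["X", L], "kXoff", "dissociation"),
            reaction(["Xa", L], [f"Xab{tag}"], "kXon", "association"),
            reaction([f"Xab{tag}"], ["Xa", L], "kXoff", "dissociation"),
            # mechanism 1: M binds lipid-bound FX/FXa at solution rates
            reaction(["M", f"Xb{tag}"], [f"M:Xb{tag}"], "kMX_on", "association"),
            reaction([f"M:Xb{tag}"], ["M", f"Xb{tag}"], "kMX_off", "dissociation"),
            reaction(["M", f"Xab{tag}"], [f"M:Xab{tag}"], "kMX_on", "association"),
            reaction([f"M:Xab{tag}"], ["M", f"Xab{tag}"], "kMX_off", "dissociation",
                     scale_keys=["gamma_MXa"]),
            # mechanism 2: lipidation of M-bound FX/FXa, association scaled by alpha
            reaction(["M:X", L], [f"M:Xb{tag}"], "kXon", "association",
                     scale_keys=["alpha"]),
            reaction([f"M:Xb{tag}"], ["M:X", L], "kXoff", "dissociation"),
            reaction(["M:Xa", L], [f"M:Xab{tag}"], "kXon", "association",
                     scale_keys=["alpha"]),
            reaction([f"M:Xab{tag}"], ["M:Xa", L], "kXoff", "dissociation"),
        ]
    rx += [
        # solution-phase emicizumab binding
        reaction(["M", "X"], ["M:X"], "kMX_on", "association"),
        reaction(["M:X"], ["M", "X"], "kMX_off", "dissociation"),
        reaction(["M", "Xa"], ["M:Xa"], "kMX_on", "association"),
        reaction(["M:Xa"], ["M", "Xa"], "kMX_off", "dissociation",
                 scale_keys=["gamma_MXa"]),
        # TF:VIIa Michaelis step and turnover
        reaction(["E", "Xb+"], ["E:Xb"], "kEX_on", "association"),
        reaction(["E:Xb"], ["E", "Xb+"], "kEX_off", "dissociation"),
        reaction(["E:Xb"], ["E", "Xab+"], "kEcat", "catalysis"),
        # mechanism 3: TF:VIIa engages M-bound FX, association scaled by beta
        reaction(["E", "M:Xb+"], ["E:M:Xb"], "kEX_on", "association",
                 scale_keys=["beta"]),
        reaction(["E:M:Xb"], ["E", "M:Xb+"], "kEX_off", "dissociation"),
        reaction(["E:M:Xb"], ["E", "M:Xab+"], "kEcat", "catalysis"),
    ]
    net = build_network(species, rx, name="one_arm")
    if params is not None:
        missing = sorted(
            {r.rate_key for r in rx if r.rate_key not in params}
            | {k for r in rx for k in r.scale_keys if k not in params}
        )
        if missing:
            raise KeyError(f"missing rates for one-arm model: {missing}")
    return net


def make_design(
    FX_nM: float,
    M_nM: float,
    lipid_uM: float = 80.0,
    TFVIIa_nM: float = 0.5,
    duration_s: float = 1800.0,
    dt_s: float = 60.0,
    lipid: LipidConfig | None = None,
    label: str = "",
) -> ExperimentDesign:
    """Assay design for the TF:VIIa system (readout: total FXa, nM)."""
    lipid = lipid or LipidConfig()
    sites = lipid.sites_nM(lipid_uM)
    conc = {
        "X": FX_nM,
        "M": M_nM,
        "E": TFVIIa_nM,
        "L+": lipid.tf_site_fraction * sites,
        "L-": (1.0 - lipid.tf_site_fraction) * sites,
    }
    return ExperimentDesign(
        initial_concentrations={k: v for k, v in conc.items() if v > 0},
        duration=duration_s,
        sample_times=np.arange(0.0, duration_s + 1e-9, dt_s),
        readout="total_FXa",
        label=label or f"one_arm_M{M_nM:g}_FX{FX_nM:g}",
        meta={
            "M_nM": M_nM, "FX_nM": FX_nM, "FIXa_nM": 0.0,
            "TFVIIa_nM": TFVIIa_nM, "lipid_uM": lipid_uM,
        },
    )


def fxa_timecourse(trajectory: Trajectory) -> np.ndarray:
    """Total FXa (nM) over all complexes and compartments."""
    return species_total(trajectory, "FXa")


def simulate_variant(
    variant: OneArmVariant,
    params: RateParameters,
    design: ExperimentDesign,
    network: ReactionNetwork | None = None,
    **solver_kw,
) -> Trajectory:
    net = network if network is not None else build_one_arm(variant, params)
    return simulate(net, variant.apply(params), design, **solver_kw)


def initial_velocities(
    fx_values: np.ndarray,
    variant: OneArmVariant,
    params: RateParameters,
    M_nM: float,
    window_s: float = 120.0,
    network: ReactionNetwork | None = None,
    design_kw: dict | None = None,
    **solver_kw,
) -> np.ndarray:
    """Early-time FXa slopes (nM/s) across an FX titration."""
    design_kw = design_kw or {}
    net = network if network is not None else build_one_arm(variant, params)
    vels = []
    for fx in fx_values:
        design = make_design(FX_nM=fx, M_nM=M_nM, dt_s=window_s / 4,
                             duration_s=max(window_s, 240.0), **design_kw)
        traj = simulate(net, variant.apply(params), design, **solver_kw)
        mask = traj.times <= window_s + 1e-9
        slope = np.polyfit(traj.times[mask], fxa_timecourse(traj)[mask], 1)[0]
        vels.append(slope)
    return np.asarray(vels)


def fit_hyperbola(fx_values: np.ndarray, velocities: np.ndarray) -> tuple[float, float]:
    """Fit v = Vmax [FX] / (KM + [FX]); returns (Vmax, apparent KM)."""
    fx = np.asarray(fx_values, dtype=float)
    v = np.asarray(velocities, dtype=float)
    p0 = (max(v.max(), 1e-12), np.median(fx))
    popt, _ = curve_fit(
        lambda s, vmax, km: vmax * s / (km + s), fx, v, p0=p0, maxfev=20000
    )
    if popt[1] <= 0:
        raise RuntimeError("apparent-KM fit did not converge to a positive KM")
    return float(popt[0]), float(popt[1])


def apparent_km_shift(
    fx_values: np.ndarray,
    params: RateParameters,
    variant: OneArmVariant,
    M_nM: float,
    window_s: float = 120.0,
    **kw,
) -> dict:
    """(Vmax, apparent KM) with and without emicizumab from an FX titration.

    Requires at least five FX concentrations spanning the apparent KM.
    """
    fx_values = np.asarray(fx_values, dtype=float)
    if fx_values.size < 5:
        raise ValueError("need >= 5 FX concentrations spanning the apparent KM")
    out = {}
    for key, m in (("without_M", 0.0), ("with_M", M_nM)):
        v = initial_velocities(fx_values, variant, params, M_nM=m,
                               window_s=window_s, **kw)
        vmax, km = fit_hyperbola(fx_values, v)
        out[key] = {"Vmax_nM_per_s": vmax, "KM_nM": km}
    out["KM_ratio"] = out["with_M"]["KM_nM"] / out["without_M"]["KM_nM"]
    out["Vmax_ratio"] = (
        out["with_M"]["Vmax_nM_per_s"] / out["without_M"]["Vmax_nM_per_s"]
    )
    return out
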