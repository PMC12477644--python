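"""Species/reaction bookkeeping, mass-action ODE assembly, and stiff simulation.

The reaction networks in this package live on three "compartments": bulk
solution, the surface of TF-bearing lipid vesicles (``lipid_plus``) and the
surface of TF-free vesicles (``lipid_minus``).  Surface binding sites are
explicit pseudo-species so that all lipid-binding proteins compete for one
free-site pool per compartment and site totals are conserved exactly.

Every species carries a composition over base proteins.  Conservation is
checked per *conservation class*: FX and FXa share a class (catalysis
converts one into the other), as do the chromogenic substrate S and the
released chromophore C; everything else conserves itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import RateParameters

SOLUTION = "solution"
LIPID_PLUS = "lipid_plus"
LIPID_MINUS = "lipid_minus"
COMPARTMENTS = (SOLUTION, LIPID_PLUS, LIPID_MINUS)

#: base protein -> conservation class
CONSERVATION_CLASS = {
    "FX": "fx_protein",
    "FXa": "fx_protein",
    "FIXa": "FIXa",
    "M": "M",
    "TFVIIa": "TFVIIa",
    "S": "substrate",
    "C": "substrate",
}


class NetworkError(ValueError):
    """Raised for invalid network definitions."""


class SimulationError(RuntimeError):
    """Raised when the stiff integrator fails; carries diagnostics."""

    def __init__(self, message: str, state=None, time=None):
        super().__init__(message)
        self.state = state
        self.time = time


@dataclass(frozen=True)
class Species:
    """A chemical species: solution protein, surface complex, or free-site pool.

    ``composition`` maps base proteins to their stoichiometric count in the
    species.  ``sites`` is the number of occupied lipid binding sites (1 for
    the free-site pseudo-species itself, whose composition is empty).
    """

    name: str
    compartment: str = SOLUTION
    composition: Mapping[str, int] = field(default_factory=dict)
    sites: int = 0

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise NetworkError(f"unknown compartment {self.compartment!r}")
        for base in self.composition:
            if base not in CONSERVATION_CLASS:
                raise NetworkError(f"unknown base protein {base!r} in {self.name}")
        if "TFVIIa" in self.composition and self.compartment != LIPID_PLUS:
            raise NetworkError(
                f"TF:VIIa-containing species {self.name!r} must live on lipid_plus"
            )
        if not self.composition and self.sites != 1:
            raise NetworkError(
                f"{self.name!r}: empty composition is reserved for free-site pools"
            )


@dataclass(frozen=True)
class Reaction:
    """An elementary mass-action reaction.

    The rate constant is ``params[rate_key] * prod(params[k] for k in
    scale_keys) * factor`` so that scalings such as alpha/beta/gamma stay
    symbolic until simulation time and can be refit without rebuilding the
    network.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_key: str
    kind: str  # association | dissociation | catalysis
    scale_keys: tuple[str, ...] = ()
    factor: float = 1.0

    def rate(self, params: RateParameters) -> float:
        k = params[self.rate_key] * self.factor
        for key in self.scale_keys:
            k *= params[key]
        return k

    def __str__(self):  # pragma: no cover - debugging aid
        fmt = lambda side: " + ".join(
            (f"{s}" if n == 1 else f"{n} {s}") for s, n in side
        )
        return f"{fmt(self.reactants)} -> {fmt(self.products)}  [{self.rate_key}]"


def reaction(
    reactants: Sequence[str],
    products: Sequence[str],
    rate_key: str,
    kind: str,
    scale_keys: Sequence[str] = (),
    factor: float = 1.0,
) -> Reaction:
    """Convenience constructor taking plain species-name lists (stoichiometry 1)."""
    return Reaction(
        reactants=tuple((s, 1) for s in reactants),
        products=tuple((s, 1) for s in products),
        rate_key=rate_key,
        kind=kind,
        scale_keys=tuple(scale_keys),
        factor=factor,
    )


class ReactionNetwork:
    """A validated set of species and elementary mass-action reactions."""

    def __init__(self, species: Sequence[Species], reactions: Sequence[Reaction],
                 name: str = ""):
        self.name = name
        self.species = list(species)
        self.reactions = list(reactions)
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise NetworkError(f"duplicate species names: {dupes}")
        self.index = {s.name: i for i, s in enumerate(self.species)}
        self._validate()
        self._build_arrays()

    # -- validation ------------------------------------------------------
    def _class_vector(self, cls: str) -> np.ndarray:
        """Stoichiometric weight of conservation class ``cls`` per species."""
        w = np.zeros(len(self.species))
        for i, sp in enumerate(self.species):
            for base, count in sp.composition.items():
                if CONSERVATION_CLASS[base] == cls:
                    w[i] += count
        return w

    def _site_vector(self, compartment: str) -> np.ndarray:
        w = np.zeros(len(self.species))
        for i, sp in enumerate(self.species):
            if sp.compartment == compartment:
                w[i] = sp.sites
        return w

    def conservation_vectors(self) -> dict[str, np.ndarray]:
        """All conserved linear combinations: protein classes and site pools."""
        classes = sorted(
            {CONSERVATION_CLASS[b] for sp in self.species for b in sp.composition}
        )
        vectors = {cls: self._class_vector(cls) for cls in classes}
        for comp in (LIPID_PLUS, LIPID_MINUS):
            vec = self._site_vector(comp)
            if vec.any():
                vectors[f"sites_{comp}"] = vec
        return vectors

    def _validate(self) -> None:
        vectors = self.conservation_vectors()
        for rx in self.reactions:
            for side in (rx.reactants, rx.products):
                for sp_name, stoich in side:
                    if sp_name not in self.index:
                        raise NetworkError(
                            f"reaction {rx} references unknown species {sp_name!r}"
                        )
                    if stoich < 1:
                        raise NetworkError(f"non-positive stoichiometry in {rx}")
            n_react = sum(n for _, n in rx.reactants)
            n_prod = sum(n for _, n in rx.products)
            if rx.kind == "association" and (n_react != 2 or n_prod != 1):
                raise NetworkError(f"association must be bimolecular -> 1: {rx}")
            if rx.kind == "dissociation" and (n_react != 1 or n_prod != 2):
                raise NetworkError(f"dissociation must be 1 -> 2: {rx}")
            if rx.kind == "catalysis" and n_react != 1:
                raise NetworkError(f"catalysis must be unimolecular: {rx}")
            for cls, w in vectors.items():
                delta = sum(n * w[self.index[s]] for s, n in rx.products) - sum(
                    n * w[self.index[s]] for s, n in rx.reactants
                )
                if abs(delta) > 1e-12:
                    raise NetworkError(
                        f"reaction {rx} violates conservation of {cls} "
                        f"(net change {delta:+g})"
                    )

    # -- compiled arrays for the ODE right-hand side ---------------------
    def _build_arrays(self) -> None:
        n_s, n_r = len(self.species), len(self.reactions)
        self._stoich = np.zeros((n_s, n_r))
        # per reaction: up to two reactant slots (index, order)
        self._ra = np.zeros(n_r, dtype=np.intp)
        self._rb = np.full(n_r, -1, dtype=np.intp)
        for j, rx in enumerate(self.reactions):
            slots: list[int] = []
            for sp_name, stoich in rx.reactants:
                i = self.index[sp_name]
                self._stoich[i, j] -= stoich
                slots.extend([i] * stoich)
            for sp_name, stoich in rx.products:
                self._stoich[self.index[sp_name], j] += stoich
            if len(slots) > 2:
                raise NetworkError(f"more than bimolecular reaction unsupported: {rx}")
            self._ra[j] = slots[0]
            if len(slots) == 2:
                self._rb[j] = slots[1]
        self._bimol = self._rb >= 0

    def rate_vector(self, params: RateParameters) -> np.ndarray:
        return np.array([rx.rate(params) for rx in self.reactions])

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "name": self.name,
            "species": [
                {
                    "name": s.name,
                    "compartment": s.compartment,
                    "composition": dict(s.composition),
                    "sites": s.sites,
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "reactants": list(map(list, rx.reactants)),
                    "products": list(map(list, rx.products)),
                    "rate_key": rx.rate_key,
                    "kind": rx.kind,
                    "scale_keys": list(rx.scale_keys),
                    "factor": rx.factor,
                }
                for rx in self.reactions
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ReactionNetwork":
        payload = json.loads(text)
        species = [
            Species(
                name=s["name"],
                compartment=s["compartment"],
                composition=s["composition"],
                sites=s["sites"],
            )
            for s in payload["species"]
        ]
        reactions = [
            Reaction(
                reactants=tuple((n, int(c)) for n, c in r["reactants"]),
                products=tuple((n, int(c)) for n, c in r["products"]),
                rate_key=r["rate_key"],
                kind=r["kind"],
                scale_keys=tuple(r["scale_keys"]),
                factor=r["factor"],
            )
            for r in payload["reactions"]
        ]
        return cls(species, reactions, name=payload.get("name", ""))


def build_network(species: Sequence[Species], reactions: Sequence[Reaction],
                  name: str = "") -> ReactionNetwork:
    """Validate and compile a reaction network (see :class:`ReactionNetwork`)."""
    return ReactionNetwork(species, reactions, name=name)


# ---------------------------------------------------------------------------
# derivatives and simulation
# ---------------------------------------------------------------------------

def assemble_derivatives(
    network: ReactionNetwork, params: RateParameters
) -> tuple[Callable, Callable]:
    """Compile the mass-action right-hand side and its Jacobian.

    Returns ``(f, jac)`` with ``f(t, y) -> dy/dt`` where fluxes are
    ``k_j * prod(y_i)`` over the (at most two) reactant slots of reaction j.
    """
    for rx in network.reactions:
        if rx.rate_key not in params:
            raise KeyError(f"rate key {rx.rate_key!r} not bound in parameters")
        for key in rx.scale_keys:
            if key not in params:
                raise KeyError(f"scale key {key!r} not bound in parameters")
    k = network.rate_vector(params)
    stoich = network._stoich
    ra, rb, bimol = network._ra, network._rb, network._bimol
    n_r = len(k)

    def f(t, y):
        flux = k * y[ra]
        flux[bimol] *= y[rb[bimol]]
        return stoich @ flux

    def jac(t, y):
        dflux = np.zeros((n_r, len(y)))
        rows = np.arange(n_r)
        # d flux_j / d y_ra = k * (y_rb if bimolecular else 1)
        da = k.copy()
        da[bimol] *= y[rb[bimol]]
        np.add.at(dflux, (rows, ra), da)
        db = k[bimol] * y[ra[bimol]]
        np.add.at(dflux, (rows[bimol], rb[bimol]), db)
        return stoich @ dflux

    return f, jac


@dataclass
class PreIncubation:
    """A first integration phase with only a subset of species present."""

    species: tuple[str, ...]
    duration: float  # s


@dataclass
class ExperimentDesign:
    """Initial concentrations (nM, keyed by species name), duration, grid, readout.

    All concentrations are final post-mix values; the assays mix equal
    volumes but report final concentrations, and preincubation phases are
    integrated at final concentrations as a documented approximation.
    """

    initial_concentrations: dict[str, float]
    duration: float  # s
    sample_times: np.ndarray | None = None
    readout: str = "total_FXa"  # or "chromophore"
    preincubation: PreIncubation | None = None
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sample_times is None:
            self.sample_times = np.arange(0.0, self.duration + 1e-9, 60.0)
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if self.sample_times[0] < 0 or self.sample_times[-1] > self.duration + 1e-9:
            raise ValueError("sample_times must lie within [0, duration]")
        for name, value in self.initial_concentrations.items():
            if value < 0:
                raise ValueError(f"negative initial concentration for {name}")


@dataclass
class Trajectory:
    """Simulated concentrations (nM) of all species over time."""

    times: np.ndarray
    values: np.ndarray  # time x species
    network: ReactionNetwork
    design: ExperimentDesign
    params: RateParameters

    def series(self, species_name: str) -> np.ndarray:
        return self.values[:, self.network.index[species_name]]

    def total(self, base_protein: str,
              compartments: Iterable[str] | None = None) -> np.ndarray:
        return species_total(self, base_protein, compartments)

    def at_time(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-6 * max(1.0, abs(t)) + 1e-9:
            raise ValueError(f"time {t} s not on the sample grid")
        return self.values[i]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (time, species)."""
        records = []
        for j, sp in enumerate(self.network.species):
            for i, t in enumerate(self.times):
                records.append(
                    (t, sp.name, sp.compartment, self.values[i, j])
                )
        return pd.DataFrame(
            records, columns=["time_s", "species", "compartment", "value_nM"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def initial_state(network: ReactionNetwork,
                  concentrations: Mapping[str, float]) -> np.ndarray:
    y0 = np.zeros(len(network.species))
    for name, value in concentrations.items():
        if name not in network.index:
            raise NetworkError(f"design species {name!r} not in network")
        y0[network.index[name]] = value
    return y0


def _integrate(f, jac, y0, t_span, t_eval, rtol, atol, method):
    sol = solve_ivp(
        f, t_span, y0, method=method, jac=jac, t_eval=t_eval, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise SimulationError(
            f"stiff solver failed: {sol.message} (t reached {sol.t[-1] if len(sol.t) else t_span[0]:g} s)",
            state=sol.y[:, -1] if sol.y.size else y0,
            time=sol.t[-1] if len(sol.t) else t_span[0],
        )
    return sol


def simulate(
    network: ReactionNetwork,
    params: RateParameters,
    design: ExperimentDesign,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the network from the design's initial state.

    If the design has a preincubation phase, that subset of species is
    integrated alone for the preincubation duration; the remaining species
    are then added and the clock restarts at t = 0.
    """
    f, jac = assemble_derivatives(network, params)
    conc = dict(design.initial_concentrations)
    if design.preincubation is not None:
        pre = design.preincubation
        pre_conc = {n: conc.pop(n) for n in pre.species if n in conc}
        y_pre = initial_state(network, pre_conc)
        sol_pre = _integrate(
            f, jac, y_pre, (0.0, pre.duration), None, rtol, atol, method
        )
        y0 = sol_pre.y[:, -1] + initial_state(network, conc)
    else:
        y0 = initial_state(network, conc)

    t_eval = design.sample_times
    sol = _integrate(
        f, jac, y0, (0.0, design.duration), t_eval, rtol, atol, method
    )
    values = sol.y.T.copy()
    return Trajectory(
        times=sol.t.copy(), values=values, network=network,
        design=design, params=params,
    )


def species_total(
    trajectory: Trajectory,
    base_protein: str,
    compartments: Iterable[str] | None = None,
) -> np.ndarray:
    """Stoichiometry-weighted total of a base protein over all species.

    Optionally restricted to a set of compartments.
    """
    if base_protein not in CONSERVATION_CLASS:
        raise KeyError(f"unknown base protein {base_protein!r}")
    comp_filter = set(compartments) if compartments is not None else None
    net = trajectory.network
    weights = np.zeros(len(net.species))
    for i, sp in enumerate(net.species):
        if comp_filter is not None and sp.compartment not in comp_filter:
            continue
        weights[i] = sp.composition.get(base_protein, 0)
    return trajectory.values @ weights


# ---------------------------------------------------------------------------
# binding-cycle thermodynamic audit
# ---------------------------------------------------------------------------

def binding_cycle_imbalances(
    network: ReactionNetwork, params: RateParameters
) -> list[dict]:
    """Report the K_D-product imbalance of every two-route binding cycle.

    A cycle is a complex reachable by two distinct two-step association
    ladders consuming the same multiset of elementary inputs, e.g. X
    binding lipid then emicizumab versus emicizumab then lipid.  For each
    such cycle the ratio of the K_D products along the two routes is
    returned; a ratio different from 1 quantifies the detailed-balance
    breaking introduced by association-only scalings such as alpha.  The
    imbalance is reported, never rejected: the scaling is a deliberate
    modeling choice.
    """
    assoc = [rx for rx in network.reactions if rx.kind == "association"]
    dissoc = [rx for rx in network.reactions if rx.kind == "dissociation"]

    def kd_of(a: Reaction) -> float | None:
        """K_D of an association step if a matching dissociation exists."""
        r_set = frozenset(s for s, _ in a.reactants)
        p = a.products[0][0]
        for d in dissoc:
            if d.reactants[0][0] == p and frozenset(s for s, _ in d.products) == r_set:
                kon, koff = a.rate(params), d.rate(params)
                if kon > 0:
                    return koff / kon
        return None

    # ladders[complex] -> list of (leaf multiset, kd_product, route description)
    ladders: dict[str, list[tuple[frozenset, float, str]]] = {}
    for a1 in assoc:
        mid = a1.products[0][0]
        kd1 = kd_of(a1)
        if kd1 is None or kd1 == 0:
            continue
        for a2 in assoc:
            names2 = [s for s, _ in a2.reactants]
            if mid not in names2:
                continue
            kd2 = kd_of(a2)
            if kd2 is None:
                continue
            top = a2.products[0][0]
            leaves = frozenset(
                [s for s, _ in a1.reactants] + [s for s in names2 if s != mid]
            )
            route = " -> ".join([" + ".join(s for s, _ in a1.reactants), mid, top])
            ladders.setdefault(top, []).append((leaves, kd1 * kd2, route))

    report = []
    for top, routes in ladders.items():
        for i in range(len(routes)):
            for j in range(i + 1, len(routes)):
                leaves_i, kd_i, route_i = routes[i]
                leaves_j, kd_j, route_j = routes[j]
                if leaves_i == leaves_j and route_i != route_j and kd_j > 0:
                    ratio = kd_i / kd_j
                    report.append(
                        {
                            "complex": top,
                            "route_a": route_i,
                            "route_b": route_j,
                            "kd_product_ratio": ratio,
                            "log10_imbalance": float(np.log10(ratio)),
                        }
                    )
    return report
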