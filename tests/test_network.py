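"""Network construction, mass-action assembly, simulation, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emikin.network import (
    ExperimentDesign,
    NetworkError,
    PreIncubation,
    Reaction,
    Species,
    assemble_derivatives,
    binding_cycle_imbalances,
    build_network,
    initial_state,
    simulate,
    species_total,
)
from emikin.one_arm import build_one_arm
from emikin.one_arm import make_design as one_arm_design
from emikin.two_arm import make_design as two_arm_design

from conftest import isotherm_complex


class TestBuildNetwork:
    def test_minimal_binding_pair(self, binding_pair):
        assert len(binding_pair.species) == 3
        assert len(binding_pair.reactions) == 2

    def test_creation_from_nothing_rejected(self):
        species = [Species("Xa", "solution", {"FXa": 1}),
                   Species("X", "solution", {"FX": 1})]
        bad = Reaction((("X", 1),), (("X", 1), ("Xa", 1)), "k", "catalysis")
        with pytest.raises(NetworkError, match="conservation"):
            build_network(species, [bad])

    def test_unknown_species_rejected(self):
        species = [Species("X", "solution", {"FX": 1})]
        bad = Reaction((("X", 1), ("ghost", 1)), (("X", 1),), "k", "association")
        with pytest.raises(NetworkError, match="unknown species"):
            build_network(species, [bad])

    def test_duplicate_names_rejected(self):
        species = [Species("X", "solution", {"FX": 1}),
                   Species("X", "solution", {"FX": 1})]
        with pytest.raises(NetworkError, match="duplicate"):
            build_network(species, [])

    def test_two_arm_network_stoichiometric_audit(self, two_arm_net):
        """Independent per-protein audit: every reaction balances every class."""
        class_of = {"FX": "fx", "FXa": "fx", "FIXa": "ixa", "M": "m",
                    "TFVIIa": "e", "S": "sub", "C": "sub"}
        by_name = {s.name: s for s in two_arm_net.species}
        for rx in two_arm_net.reactions:
            balance: dict[str, int] = {}
            for side, sign in ((rx.reactants, -1), (rx.products, +1)):
                for name, stoich in side:
                    sp = by_name[name]
                    for base, count in sp.composition.items():
                        key = class_of[base]
                        balance[key] = balance.get(key, 0) + sign * stoich * count
                    balance["sites"] = (balance.get("sites", 0)
                                        + sign * stoich * sp.sites)
            assert all(v == 0 for v in balance.values()), f"unbalanced: {rx}"


class TestDerivatives:
    def test_null_rates_zero_derivative(self, binding_pair, params):
        zero = params.with_updates(kMX_on=0.0, kMX_off=0.0)
        f, _ = assemble_derivatives(binding_pair, zero)
        y = np.array([100.0, 50.0, 10.0])
        assert np.all(f(0.0, y) == 0.0)

    def test_single_term_mass_action(self, params):
        """X = 100 nM, L+ = 10 nM, kXon = 0.01 and no other flux: dX/dt = -10."""
        net = build_one_arm()
        overrides = {k: 0.0 for k in params}
        overrides.update(kXon=0.01, gamma_MXa=1.0)
        p = params.with_updates(**overrides)
        f, _ = assemble_derivatives(net, p)
        y = np.zeros(len(net.species))
        y[net.index["X"]] = 100.0
        y[net.index["L+"]] = 10.0
        assert f(0.0, y)[net.index["X"]] == pytest.approx(-10.0, abs=1e-12)

    def test_one_arm_fx_derivative_expression(self, params):
        """dX/dt carries exactly the lipid-on/off and M-on/off terms."""
        net = build_one_arm()
        rng = np.random.default_rng(0)
        y = rng.uniform(0.1, 50.0, size=len(net.species))
        f, _ = assemble_derivatives(net, params)
        i = {n: net.index[n] for n in
             ("X", "L+", "L-", "Xb+", "Xb-", "M", "M:X")}
        expected = (
            -params["kXon"] * y[i["X"]] * y[i["L+"]]
            + params["kXoff"] * y[i["Xb+"]]
            - params["kXon"] * y[i["X"]] * y[i["L-"]]
            + params["kXoff"] * y[i["Xb-"]]
            - params["kMX_on"] * y[i["X"]] * y[i["M"]]
            + params["kMX_off"] * y[i["M:X"]]
        )
        assert f(0.0, y)[i["X"]] == pytest.approx(expected, rel=1e-12)

    def test_derivative_matches_flux_accumulation_oracle(self, two_arm_net, params):
        """Brute-force per-reaction flux loop reproduces the compiled RHS."""
        rng = np.random.default_rng(7)
        y = rng.uniform(0.0, 100.0, size=len(two_arm_net.species))
        f, jac = assemble_derivatives(two_arm_net, params)
        expected = np.zeros_like(y)
        for rx in two_arm_net.reactions:
            flux = rx.rate(params)
            for name, stoich in rx.reactants:
                flux *= y[two_arm_net.index[name]] ** stoich
            for name, stoich in rx.reactants:
                expected[two_arm_net.index[name]] -= stoich * flux
            for name, stoich in rx.products:
                expected[two_arm_net.index[name]] += stoich * flux
        np.testing.assert_allclose(f(0.0, y), expected, rtol=1e-8, atol=1e-10)
        # Jacobian against central finite differences
        J = jac(0.0, y)
        h = 1e-6
        for col in rng.choice(len(y), size=5, replace=False):
            yp, ym = y.copy(), y.copy()
            yp[col] += h
            ym[col] -= h
            fd = (f(0.0, yp) - f(0.0, ym)) / (2 * h)
            np.testing.assert_allclose(J[:, col], fd, rtol=1e-4, atol=1e-6)

    def test_unbound_rate_key_errors(self, binding_pair):
        from emikin.params import RateParameters
        with pytest.raises(KeyError, match="kMX_off"):
            assemble_derivatives(binding_pair, RateParameters(kMX_on=1.0))


class TestSimulate:
    def test_binding_isotherm_equilibrium(self, binding_pair, params):
        """400 + 140 nM at K_D 56 nM equilibrates at 116.9 nM complex."""
        design = ExperimentDesign(
            initial_concentrations={"M": 400.0, "X": 140.0},
            duration=2e5, sample_times=np.array([0.0, 2e5]),
        )
        traj = simulate(binding_pair, params, design)
        expected = isotherm_complex(400.0, 140.0, 56.0)
        assert expected == pytest.approx(116.9, abs=0.05)
        assert traj.series("M:X")[-1] == pytest.approx(expected, rel=1e-3)

    def test_exponential_relaxation_rate(self, binding_pair, params):
        """Approach to binding equilibrium decays at kon(A0+B0-2ABeq)+koff."""
        a0, b0 = 400.0, 140.0
        kd = params.kd("kMX_on", "kMX_off")
        ab_eq = isotherm_complex(a0, b0, kd)
        rate = params["kMX_on"] * (a0 + b0 - 2 * ab_eq) + params["kMX_off"]
        # measure deep in the linear regime, where the quadratic flux term
        # of the bilinear ODE no longer distorts the decay
        t1, t2 = 8.0 / rate, 10.0 / rate
        design = ExperimentDesign(
            initial_concentrations={"M": a0, "X": b0},
            duration=t2, sample_times=np.array([0.0, t1, t2]),
        )
        traj = simulate(binding_pair, params, design, rtol=1e-11, atol=1e-14)
        d1 = ab_eq - traj.series("M:X")[1]
        d2 = ab_eq - traj.series("M:X")[2]
        measured = np.log(d1 / d2) / (t2 - t1)
        assert measured == pytest.approx(rate, rel=1e-3)

    def test_conservation_along_trajectory(self, two_arm_net, params):
        design = two_arm_design(FX_nM=140, FIXa_nM=1, M_nM=400, lipid_uM=8,
                                duration_s=600)
        traj = simulate(two_arm_net, params, design)
        y0 = traj.values[0]
        for cls, w in two_arm_net.conservation_vectors().items():
            total0 = w @ y0
            if total0 == 0:
                continue
            totals = traj.values @ w
            np.testing.assert_allclose(totals, total0, rtol=1e-6,
                                       err_msg=f"class {cls} drifts")

    def test_nonnegative_concentrations(self, two_arm_net, params):
        design = two_arm_design(FX_nM=140, FIXa_nM=1, M_nM=3600, lipid_uM=80,
                                duration_s=1800)
        traj = simulate(two_arm_net, params, design)
        assert traj.values.min() >= -1e-9

    def test_absent_species_equivalent_to_reduced_network(self, params):
        """Emicizumab = 0 in the one-arm model matches the M-free subnetwork."""
        net = build_one_arm()
        design = one_arm_design(FX_nM=140, M_nM=0, lipid_uM=8, duration_s=600)
        full = simulate(net, params, design)
        keep = [s for s in net.species if "M" not in s.composition]
        names = {s.name for s in keep}
        sub_rx = [r for r in net.reactions
                  if {n for n, _ in r.reactants + r.products} <= names]
        sub = build_network(keep, sub_rx)
        reduced = simulate(sub, params, design)
        np.testing.assert_allclose(
            species_total(full, "FXa"), species_total(reduced, "FXa"),
            rtol=1e-6, atol=1e-9,
        )

    def test_preincubation_runs_first_phase(self, binding_pair, params):
        """Preincubating M alone delays complex formation vs plain mixing."""
        base = dict(initial_concentrations={"M": 400.0, "X": 140.0},
                    duration=30.0, sample_times=np.array([0.0, 30.0]))
        plain = simulate(binding_pair, params, ExperimentDesign(**base))
        pre = simulate(binding_pair, params, ExperimentDesign(
            **base, preincubation=PreIncubation(species=("M",), duration=300.0)))
        # M alone cannot form complex; both runs start the mix identically
        np.testing.assert_allclose(pre.series("M:X"), plain.series("M:X"),
                                   rtol=1e-6)
        pre2 = simulate(binding_pair, params, ExperimentDesign(
            **base, preincubation=PreIncubation(species=("M", "X"),
                                                duration=300.0)))
        assert pre2.series("M:X")[0] > plain.series("M:X")[0]

    def test_species_total_initial_condition(self, two_arm_net, params):
        design = two_arm_design(FX_nM=140, FIXa_nM=1, M_nM=400, lipid_uM=8,
                                duration_s=120)
        traj = simulate(two_arm_net, params, design)
        assert species_total(traj, "M")[0] == pytest.approx(400.0)
        with pytest.raises(KeyError):
            species_total(traj, "thrombin")


class TestSerialization:
    def test_json_roundtrip_preserves_dynamics(self, two_arm_net, params):
        from emikin.network import ReactionNetwork
        clone = ReactionNetwork.from_json(two_arm_net.to_json())
        assert [s.name for s in clone.species] == [s.name for s in
                                                   two_arm_net.species]
        design = two_arm_design(FX_nM=140, FIXa_nM=1, M_nM=400, lipid_uM=8,
                                duration_s=300)
        a = simulate(two_arm_net, params, design)
        b = simulate(clone, params, design)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_trajectory_tidy_export(self, binding_pair, params, tmp_path):
        design = ExperimentDesign(
            initial_concentrations={"M": 10.0, "X": 5.0}, duration=10.0,
            sample_times=np.array([0.0, 10.0]))
        traj = simulate(binding_pair, params, design)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        import pandas as pd
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["time_s", "species", "compartment",
                                       "value_nM"]
        assert len(frame) == 2 * 3


class TestCycleAudit:
    def test_alpha_imbalance_reported(self, two_arm_net, params):
        report = binding_cycle_imbalances(two_arm_net, params)
        by_complex = {r["complex"]: r for r in report}
        # lipidation of M-bound FX: the two routes differ by exactly alpha
        assert by_complex["M:Xb"]["kd_product_ratio"] == pytest.approx(
            params["alpha"])
        # solution ternary assembly is thermodynamically consistent
        assert by_complex["IXa:M:X"]["kd_product_ratio"] == pytest.approx(1.0)


@settings(max_examples=15, deadline=None)
@given(
    kon=st.floats(1e-5, 1e-2), koff=st.floats(1e-3, 10.0),
    a0=st.floats(1.0, 500.0), b0=st.floats(1.0, 500.0),
)
def test_binding_pair_conservation_property(kon, koff, a0, b0):
    """Mass conservation and the isotherm hold across random rate constants."""
    from emikin.params import RateParameters

    species = [
        Species("X", "solution", {"FX": 1}),
        Species("M", "solution", {"M": 1}),
        Species("M:X", "solution", {"M": 1, "FX": 1}),
    ]
    rx = [
        Reaction((("M", 1), ("X", 1)), (("M:X", 1),), "kMX_on", "association"),
        Reaction((("M:X", 1),), (("M", 1), ("X", 1)), "kMX_off", "dissociation"),
    ]
    net = build_network(species, rx)
    p = RateParameters(kMX_on=kon, kMX_off=koff)
    horizon = 20.0 / min(koff, kon * (a0 + b0))  # several relaxation times
    design = ExperimentDesign(
        initial_concentrations={"M": a0, "X": b0}, duration=horizon,
        sample_times=np.array([0.0, horizon / 2, horizon]))
    traj = simulate(net, p, design)
    m_tot = traj.series("M") + traj.series("M:X")
    x_tot = traj.series("X") + traj.series("M:X")
    np.testing.assert_allclose(m_tot, a0, rtol=1e-6)
    np.testing.assert_allclose(x_tot, b0, rtol=1e-6)
    assert traj.series("M:X")[-1] == pytest.approx(
        isotherm_complex(a0, b0, koff / kon), rel=1e-3, abs=1e-6)
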