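"""Rule engine: RO5, Golden Triangle, 3/75, CNS cutoffs, QED."""

import dataclasses
import math

import numpy as np
import pytest

from chemprofiler.descriptors import DescriptorVector
from chemprofiler.rules import (
    GOLDEN_TRIANGLE_VERTICES,
    cns_like,
    evaluate_rules,
    golden_triangle,
    load_qed_model,
    pfizer_3_75,
    qed_from_properties,
    ro5,
    ro5_pair_frequencies,
)


def make_dv(**overrides):
    base = dict(
        mw=300.0, logp=2.0, logd_ph7=2.0, tpsa=60.0, hbd=1, hba=4,
        rotatable_bonds=4, rigid_bonds=10, rings=2, aromatic_rings=1,
        max_ring_size=6, stereocenters=0, fsp3=0.3, formal_charges_ph7=0,
        heavy_atoms=22, logs=-3.0, shape_index=0.6, flexibility=0.3,
    )
    base.update(overrides)
    return DescriptorVector(**base)


class TestRo5:
    def test_clean_profile_no_violations(self):
        assert ro5(make_dv(mw=400, logp=3, hba=5, hbd=2)) == (0, frozenset())

    def test_large_lipophilic_profile_violates_mw_only(self):
        # a typical PPI-inhibitor mean profile: heavy but otherwise inside RO5
        n, props = ro5(make_dv(mw=521, logp=4.8, hba=7, hbd=2))
        assert n == 1
        assert props == frozenset({"MW"})

    def test_all_four_broken(self):
        n, props = ro5(make_dv(mw=600, logp=6, hba=11, hbd=6))
        assert n == 4
        assert props == frozenset({"MW", "logP", "HBA", "HBD"})

    def test_cutoffs_are_inclusive(self):
        assert ro5(make_dv(mw=500, logp=5, hba=10, hbd=5))[0] == 0
        assert ro5(make_dv(mw=500.01, logp=5, hba=10, hbd=5))[0] == 1

    def test_monotone_in_each_descriptor(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            dv = make_dv(
                mw=float(rng.uniform(100, 900)), logp=float(rng.uniform(-2, 9)),
                hba=int(rng.integers(0, 16)), hbd=int(rng.integers(0, 10)),
            )
            n0 = ro5(dv)[0]
            assert 0 <= n0 <= 4
            worse = dataclasses.replace(dv, mw=dv.mw + 200, logp=dv.logp + 3,
                                        hba=dv.hba + 6, hbd=dv.hbd + 4)
            assert ro5(worse)[0] >= n0


class TestRo5PairFrequencies:
    def test_single_dominant_pair(self):
        sets = [frozenset({"MW", "logP"})] * 3
        assert ro5_pair_frequencies(sets) == [(("MW", "logP"), 1.0)]

    def test_triple_violation_contributes_three_pairs(self):
        sets = [frozenset({"MW", "logP", "HBA"})]
        result = dict(ro5_pair_frequencies(sets))
        assert result == {
            ("HBA", "MW"): 1.0, ("HBA", "logP"): 1.0, ("MW", "logP"): 1.0,
        }

    def test_mixed_set_matches_brute_force(self):
        import itertools

        rng = np.random.default_rng(3)
        props = ["MW", "logP", "HBA", "HBD"]
        sets = [
            frozenset(rng.choice(props, size=rng.integers(0, 5), replace=False))
            for _ in range(100)
        ]
        multi = [s for s in sets if len(s) >= 2]
        brute = {}
        for s in multi:
            for pair in itertools.combinations(sorted(s), 2):
                brute[pair] = brute.get(pair, 0) + 1
        expected = {p: c / len(multi) for p, c in brute.items()}
        assert dict(ro5_pair_frequencies(sets)) == pytest.approx(expected)

    def test_no_multiviolation_reports(self):
        assert ro5_pair_frequencies([frozenset(), frozenset({"MW"})]) == []

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            ro5_pair_frequencies([])


def triangle_halfplane_oracle(logd, mw):
    """Independent point-in-triangle test via signed areas (half-planes)."""
    (x1, y1), (x2, y2), (x3, y3) = GOLDEN_TRIANGLE_VERTICES
    p = (logd, mw)

    def side(a, b, pt):
        return (b[0] - a[0]) * (pt[1] - a[1]) - (b[1] - a[1]) * (pt[0] - a[0])

    d1 = side((x1, y1), (x2, y2), p)
    d2 = side((x2, y2), (x3, y3), p)
    d3 = side((x3, y3), (x1, y1), p)
    has_neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
    has_pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
    return not (has_neg and has_pos)


class TestGoldenTriangle:
    @pytest.mark.parametrize(
        "logd,mw,inside",
        [
            (1.5, 450, True),    # apex, boundary inclusive
            (1.5, 325, True),    # mid-triangle
            (6.0, 300, False),   # right edge at MW 300 is logD 3.6
            (-2.0, 200, True),   # baseline corner
            (5.0, 200, True),    # baseline corner
            (0.0, 150, False),   # below the baseline
            (3.25, 325, True),   # exactly on the right edge
            (3.26, 325, False),
        ],
    )
    def test_known_points(self, logd, mw, inside):
        assert golden_triangle(make_dv(mw=mw, logd_ph7=logd)) is inside

    def test_agrees_with_halfplane_oracle(self):
        rng = np.random.default_rng(12)
        logd = rng.uniform(-5, 9, size=10_000)
        mw = rng.uniform(100, 600, size=10_000)
        for d, m in zip(logd, mw):
            assert golden_triangle(make_dv(mw=float(m), logd_ph7=float(d))) == \
                triangle_halfplane_oracle(float(d), float(m)), (d, m)


class TestPfizer375:
    @pytest.mark.parametrize(
        "logp,tpsa,risk",
        [(4, 50, True), (2, 100, False), (3, 75, False), (3.01, 74.9, True),
         (4, 75, False), (3, 50, False)],
    )
    def test_strict_boundary_convention(self, logp, tpsa, risk):
        assert pfizer_3_75(make_dv(logp=logp, tpsa=tpsa)) is risk


class TestCnsLike:
    @pytest.mark.parametrize(
        "mw,tpsa,hba,ok",
        [(300, 60, 3, True), (521, 101, 7, False), (450, 80, 5, True),
         (450.01, 80, 5, False), (450, 80.01, 5, False), (450, 80, 6, False)],
    )
    def test_inclusive_cutoffs(self, mw, tpsa, hba, ok):
        assert cns_like(make_dv(mw=mw, tpsa=tpsa, hba=hba)) is ok


class TestQed:
    def test_argmax_vector_scores_one(self):
        model = load_qed_model()
        assert model.qed(model.argmax_vector()) == pytest.approx(1.0, abs=1e-9)

    def test_bounded_on_random_grid(self):
        model = load_qed_model()
        rng = np.random.default_rng(5)
        for _ in range(2000):
            props = {
                "mw": float(rng.uniform(0, 1200)),
                "logp": float(rng.uniform(-6, 12)),
                "hba": float(rng.integers(0, 20)),
                "hbd": float(rng.integers(0, 12)),
                "tpsa": float(rng.uniform(0, 350)),
                "rotatable_bonds": float(rng.integers(0, 25)),
                "aromatic_rings": float(rng.integers(0, 8)),
                "alerts": float(rng.integers(0, 10)),
            }
            assert 0.0 < model.qed(props) <= 1.0

    def test_weight_rescaling_invariance(self):
        data_props = {
            "mw": 350.0, "logp": 2.5, "hba": 5.0, "hbd": 1.0, "tpsa": 70.0,
            "rotatable_bonds": 4.0, "aromatic_rings": 2.0, "alerts": 1.0,
        }
        model = load_qed_model()
        q1 = model.qed(data_props)
        from chemprofiler.rules import QEDModel

        scaled = QEDModel(model.ads_params, {k: 7.3 * w for k, w in model.weights.items()})
        assert scaled.qed(data_props) == pytest.approx(q1, abs=1e-10)

    def test_unit_weights_reduce_to_geometric_mean(self):
        model = load_qed_model("unit")
        props = model.argmax_vector()
        props["mw"] = 500.0
        props["alerts"] = 2.0
        ds = [model.desirability(p, props[p]) for p in model.PROPERTIES]
        expected = math.exp(sum(math.log(min(d, 1.0)) for d in ds) / len(ds))
        assert model.qed(props) == pytest.approx(expected, abs=1e-12)

    def test_more_alerts_never_increase_qed(self):
        model = load_qed_model()
        props = model.argmax_vector()
        prev = model.qed(props)
        for alerts in range(1, 10):
            props["alerts"] = float(alerts)
            cur = model.qed(props)
            assert cur <= prev + 1e-12
            prev = cur

    def test_desirability_matches_published_reference(self):
        """Cross-check our ADS evaluation against the reference implementation
        of the published desirability functions."""
        from rdkit.Chem import QED as rdkit_qed

        model = load_qed_model()
        name_map = {
            "mw": "MW", "logp": "ALOGP", "hba": "HBA", "hbd": "HBD",
            "tpsa": "PSA", "rotatable_bonds": "ROTB",
            "aromatic_rings": "AROM", "alerts": "ALERTS",
        }
        grids = {
            "mw": np.linspace(50, 800, 40), "logp": np.linspace(-4, 8, 40),
            "hba": np.arange(0, 15), "hbd": np.arange(0, 8),
            "tpsa": np.linspace(0, 250, 40), "rotatable_bonds": np.arange(0, 18),
            "aromatic_rings": np.arange(0, 6), "alerts": np.arange(0, 8),
        }
        for prop, grid in grids.items():
            ref_params = rdkit_qed.adsParameters[name_map[prop]]
            for x in grid:
                ours = model.desirability(prop, float(x))
                ref = rdkit_qed.ads(float(x), ref_params)  # already max-normalized
                assert ours == pytest.approx(ref, rel=1e-5, abs=1e-9), (prop, x)

    def test_unknown_weight_set_errors(self):
        with pytest.raises(ValueError):
            load_qed_model("bogus")


def test_evaluate_rules_bundles_consistent_report():
    dv = make_dv(mw=521, logp=4.8, hba=7, hbd=2, tpsa=101, logd_ph7=3.5)
    report = evaluate_rules(dv, alert_count=0)
    assert report.ro5_violations == len(report.ro5_violated_props) == 1
    assert report.ro5_compliant
    assert not report.cns_like
    assert 0.0 < report.qed <= 1.0
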