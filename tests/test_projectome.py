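import numpy as np
import pandas as pd
import pytest

from projectomics.projectome import (
    ConnectomeMatrix,
    build_connectome,
    call_target,
    hemispheric_symmetry,
    laminar_profile,
    weak_target_summary,
)


def _records(rows):
    df = pd.DataFrame(
        rows,
        columns=["cell_id", "cell_type", "source_area", "target_region",
                 "layer", "hemisphere", "axon_length", "n_terminals",
                 "max_branch_order"],
    )
    df["passes_filter"] = call_target(
        df["axon_length"], df["n_terminals"], df["max_branch_order"]
    )
    return df


def _meta(cell_ids, cell_type="T", source_area="S"):
    return pd.DataFrame(
        {"cell_type": cell_type, "source_area": source_area},
        index=pd.Index(cell_ids, name="cell_id"),
    )


class TestCallTarget:
    @pytest.mark.parametrize(
        "axl,terms,order,expected",
        [
            (1500.0, 0, 5, False),   # long passing fiber, no terminal
            (500.0, 1, 1, False),    # mid-length without second-order bif
            (500.0, 2, 2, True),     # mid-length with terminal + 2nd-order bif
            (15.0, 3, 3, False),     # below the short threshold
            (1500.0, 1, 0, True),    # long with a terminal
            (20.0, 1, 2, True),      # boundary: 20 μm inside the band
            (1000.0, 1, 1, False),   # boundary: 1000 μm still in the band
        ],
    )
    def test_filter_rules(self, axl, terms, order, expected):
        assert call_target(axl, terms, order) is expected

    def test_monotone_in_long_threshold(self):
        rng = np.random.default_rng(0)
        axl = rng.uniform(0, 3000, 500)
        terms = rng.integers(0, 4, 500)
        order = rng.integers(0, 5, 500)
        passing = [
            call_target(axl, terms, order, long_threshold=t).sum()
            for t in (500.0, 1000.0, 2000.0, 3000.0)
        ]
        assert passing == sorted(passing, reverse=True)


class TestBuildConnectome:
    def test_arithmetic(self):
        rows = [
            ("c1", "T", "S", "R", None, "ipsi", 1000.0, 1, 2),
            ("c2", "T", "S", "R", None, "ipsi", 3000.0, 1, 0),
            ("c3", "T", "S", "R", None, "ipsi", 10.0, 1, 2),
            ("c4", "T", "S", "S", None, "ipsi", 5000.0, 3, 4),
        ]
        conn = build_connectome(_records(rows), _meta(["c1", "c2", "c3", "c4"]))
        r = conn.table.set_index("target_region")
        assert r.loc["R", "TargProb"] == pytest.approx(50.0)
        assert r.loc["R", "TargStren"] == pytest.approx(2000.0)
        assert conn.n_cells[("T", "S")] == 4

    def test_local_targprob_100(self, default_connectome):
        conn, _, _ = default_connectome
        t = conn.table
        for ctype, src in conn.n_cells.index:
            local = t[(t.cell_type == ctype) & (t.target_region == src)
                      & (t.hemisphere == "ipsi")]
            assert local["TargProb"].iloc[0] >= 99.0

    def test_invariant_under_cell_order(self):
        rows = [
            ("c1", "T", "S", "R", None, "ipsi", 2000.0, 1, 2),
            ("c2", "T", "S", "R", None, "ipsi", 500.0, 2, 3),
            ("c3", "T", "S", "Q", None, "ipsi", 800.0, 1, 2),
        ]
        a = build_connectome(_records(rows), _meta(["c1", "c2", "c3"]))
        b = build_connectome(_records(rows[::-1]), _meta(["c3", "c1", "c2"]))
        pd.testing.assert_frame_equal(
            a.table.sort_values(["target_region"]).reset_index(drop=True),
            b.table.sort_values(["target_region"]).reset_index(drop=True),
        )

    def test_unlabeled_cells_warned_and_dropped(self):
        meta = _meta(["c1", "c2"])
        meta.loc["c2", "cell_type"] = None
        rows = [("c1", "T", "S", "R", None, "ipsi", 2000.0, 1, 2),
                ("c2", "T", "S", "R", None, "ipsi", 2000.0, 1, 2)]
        with pytest.warns(UserWarning, match="no type label"):
            conn = build_connectome(_records(rows), meta)
        assert conn.n_cells[("T", "S")] == 1

    def test_target_number_matches_brute_force(self, default_connectome):
        conn, records, _ = default_connectome
        passing = records[records["passes_filter"]]
        for (ctype, src), expected in conn.target_number.items():
            g = passing[passing["cell_type"] == ctype]
            brute = g.groupby(["target_region", "hemisphere"],
                              observed=True).ngroups
            assert expected == brute


class TestWeakTargets:
    def _matrix(self, probs, strens):
        table = pd.DataFrame(
            {
                "cell_type": "T", "source_area": "S",
                "target_region": [f"R{i}" for i in range(len(probs))],
                "hemisphere": "ipsi", "TargProb": probs,
                "TargStren": strens, "n_pass": 1,
            }
        )
        return ConnectomeMatrix(table, pd.Series(dtype=int), pd.Series(dtype=int))

    def test_all_strong(self):
        m = self._matrix([50.0, 80.0], [2000.0, 3000.0])
        assert weak_target_summary(m, 1000.0, 2.4) == (1.0, 1.0)

    def test_zero_cut(self):
        m = self._matrix([50.0, 1.0], [500.0, 100.0])
        assert weak_target_summary(m, 0.0, 0.0) == (1.0, 1.0)

    def test_planted_weak_fraction(self):
        rng = np.random.default_rng(4)
        n = 200
        weak = rng.random(n) < 0.10
        strens = np.where(weak, rng.uniform(100, 900, n),
                          rng.uniform(1100, 5000, n))
        probs = np.where(weak, rng.uniform(0.1, 2.0, n),
                         rng.uniform(3.0, 100.0, n))
        frac_axl, frac_prob = weak_target_summary(
            self._matrix(probs, strens), 1000.0, 2.4
        )
        planted = 1 - weak.mean()
        assert frac_axl == pytest.approx(planted, abs=1e-12)
        assert frac_prob == pytest.approx(planted, abs=1e-12)


class TestLaminarProfile:
    def test_single_layer_indicator(self):
        recs = _records([("c1", "T", "S", "R", "L5", "ipsi", 2000.0, 1, 2)])
        profile, ok = laminar_profile(recs, "R", n_cells=1)
        assert ok and profile.to_dict() == {"L5": 1.0}

    def test_two_layer_normalization(self):
        rows = []
        for i in range(5):  # 40% of cells hit L2/3 (2/5), 20% hit L5 (1/5)
            if i < 2:
                rows.append((f"c{i}", "T", "S", "R", "L2/3", "ipsi", 2000.0, 1, 2))
        rows.append(("c0", "T", "S", "R", "L5", "ipsi", 2000.0, 1, 2))
        profile, ok = laminar_profile(_records(rows), "R", n_cells=5)
        assert ok
        assert profile["L2/3"] == pytest.approx(1.0)
        assert profile["L5"] == pytest.approx(0.5)
        renorm = profile / profile.max()
        pd.testing.assert_series_equal(profile, renorm)

    def test_all_zero_flagged(self):
        recs = _records([("c1", "T", "S", "R", "L5", "ipsi", 10.0, 1, 2)])
        profile, ok = laminar_profile(recs, "R", n_cells=1)
        assert not ok and (profile == 0).all()


class TestHemisphericSymmetry:
    def _matrix(self, ipsi, contra):
        rows = []
        for i, (a, b) in enumerate(zip(ipsi, contra)):
            rows.append({"cell_type": "T", "source_area": "S",
                         "target_region": f"R{i}", "hemisphere": "ipsi",
                         "TargProb": a, "TargStren": 1.0, "n_pass": 1})
            rows.append({"cell_type": "T", "source_area": "S",
                         "target_region": f"R{i}", "hemisphere": "contra",
                         "TargProb": b, "TargStren": 1.0, "n_pass": 1})
        return ConnectomeMatrix(pd.DataFrame(rows), pd.Series(dtype=int),
                                pd.Series(dtype=int))

    def test_identical_vectors(self):
        m = self._matrix([10, 40, 90.0], [10, 40, 90.0])
        r, p, ok = hemispheric_symmetry(m, "T", "S", n_perm=200)
        assert ok and r == pytest.approx(1.0)

    def test_anti_ordered_vectors(self):
        m = self._matrix([10, 50, 90.0], [90, 50, 10.0])
        r, _, ok = hemispheric_symmetry(m, "T", "S", n_perm=200)
        assert ok and r == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        m = self._matrix([10, 10, 10.0], [5, 40, 80.0])
        r, p, ok = hemispheric_symmetry(m, "T", "S", n_perm=10)
        assert not ok and np.isnan(r)

    def test_noise_recovery_within_band(self):
        # contra = ipsi + Gaussian noise: expected r = 1/sqrt(1 + s2/var)
        rng = np.random.default_rng(12)
        ipsi = rng.uniform(0, 100, 300)
        sigma = 15.0
        contra = np.clip(ipsi + rng.normal(0, sigma, 300), 0, None)
        planted = 1 / np.sqrt(1 + sigma**2 / ipsi.var())
        r, p, ok = hemispheric_symmetry(self._matrix(ipsi, contra), "T", "S",
                                        n_perm=500)
        assert ok and abs(r - planted) < 0.05
        assert p < 0.01

    def test_contra_strength_ratio_recovered(self, default_population,
                                             default_connectome):
        # planted bilateral target with contra mean AxL = 0.5 x ipsi
        conn, _, _ = default_connectome
        t = conn.table.set_index(["cell_type", "target_region", "hemisphere"])
        ipsi = t.loc[("IT_like", "A3", "ipsi"), "TargStren"]
        contra = t.loc[("IT_like", "A3", "contra"), "TargStren"]
        assert contra / ipsi == pytest.approx(0.5, rel=0.15)
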