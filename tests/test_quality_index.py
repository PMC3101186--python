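"""Standardized-distance indices, robust array summaries and GCR."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from snpqc.af_reference import AFReference
from snpqc.containers import AlleleFrequencyMatrix, GenotypeMatrix
from snpqc.errors import InputError
from snpqc.quality_index import (
    array_qi,
    compute_gcr,
    merge_array_qi,
    nearest_mean_q,
    snp_qi_genotype,
    snp_qi_nearest,
    summarize,
    trimmed_mean,
    winsorized_mean,
)
from snpqc.simulation import simulate_arrays, synth_population

from conftest import make_annotation


def reference_from_cells(cells, ann=None):
    """cells: list of (snp_id, genotype, mean, sd[, eligible])."""
    rows = []
    for cell in cells:
        snp, g, mean, sd = cell[:4]
        eligible = cell[4] if len(cell) > 4 else True
        rows.append(
            {
                "snp_id": snp,
                "chromosome": "1",
                "position_bp": 1000,
                "array_label": "Nsp",
                "genotype": g,
                "mean": mean,
                "sd": sd,
                "n": 50,
                "eligible": eligible,
            }
        )
    return AFReference(table=pd.DataFrame(rows))


def single_snp_af(lam, ann=None):
    ann = make_annotation(1) if ann is None else ann
    return AlleleFrequencyMatrix(
        annotation=ann,
        af=pd.DataFrame({"s1": [lam]}, index=ann["snp_id"], dtype=float),
    )


class TestGenotypeIndex:
    def _inputs(self, lam, call):
        ann = make_annotation(1)
        af = single_snp_af(lam, ann)
        geno = GenotypeMatrix(
            annotation=ann, calls=pd.DataFrame({"s1": [call]}, index=ann["snp_id"])
        )
        ref = reference_from_cells(
            [("rs1", "AA", 0.95, 0.05), ("rs1", "AB", 0.5, 0.1), ("rs1", "BB", 0.05, 0.05)]
        )
        return af, geno, ref

    def test_zero_distance_at_reference_mean(self):
        af, geno, ref = self._inputs(0.5, "AB")
        q = snp_qi_genotype(af, geno, ref).q.iloc[0, 0]
        assert q == 0.0

    def test_standardized_distance_arithmetic(self):
        af, geno, ref = self._inputs(0.7, "AB")
        q = snp_qi_genotype(af, geno, ref).q.iloc[0, 0]
        assert q == pytest.approx(2.0)  # |0.7 - 0.5| / 0.1

    def test_no_call_gives_missing(self):
        af, geno, ref = self._inputs(0.7, "NC")
        assert np.isnan(snp_qi_genotype(af, geno, ref).q.iloc[0, 0])

    def test_ineligible_reference_cell_gives_missing(self):
        ann = make_annotation(1)
        af = single_snp_af(0.7, ann)
        geno = GenotypeMatrix(
            annotation=ann, calls=pd.DataFrame({"s1": ["AB"]}, index=ann["snp_id"])
        )
        ref = reference_from_cells([("rs1", "AB", 0.5, 0.1, False)])
        assert np.isnan(snp_qi_genotype(af, geno, ref).q.iloc[0, 0])

    @given(
        shift=st.floats(-0.3, 0.3),
        scale=st.floats(0.2, 3.0),
        lam=st.floats(0.05, 0.95),
    )
    @settings(max_examples=50, deadline=None)
    def test_location_scale_invariance(self, shift, scale, lam):
        # q is unchanged by an affine map applied consistently to lambda,
        # mu and sigma (as long as values stay inside [0, 1])
        mu, sigma = 0.5, 0.1
        q0 = abs(lam - mu) / sigma
        lam2 = np.clip(shift + scale * lam, 0, 1)
        mu2 = shift + scale * mu
        if not 0 <= mu2 <= 1 or lam2 != shift + scale * lam:
            return
        q1 = abs(lam2 - mu2) / (scale * sigma)
        assert q1 == pytest.approx(q0, rel=1e-9)


class TestNearestMeanIndex:
    def test_picks_nearest_mean(self):
        ann = make_annotation(1)
        af = single_snp_af(0.9, ann)
        ref = reference_from_cells(
            [("rs1", "AA", 0.95, 0.05), ("rs1", "AB", 0.5, 0.1), ("rs1", "BB", 0.05, 0.05)]
        )
        q = snp_qi_nearest(af, ref).q.iloc[0, 0]
        assert q == pytest.approx(1.0)  # |0.9 - 0.95| / 0.05

    def test_tie_breaks_toward_smaller_q(self):
        ann = make_annotation(1)
        af = single_snp_af(0.725, ann)  # midway between 0.95 and 0.5
        ref = reference_from_cells(
            [("rs1", "AA", 0.95, 0.05), ("rs1", "AB", 0.5, 0.1)]
        )
        q = snp_qi_nearest(af, ref).q.iloc[0, 0]
        assert q == pytest.approx(0.225 / 0.1)  # larger sigma wins

    def test_no_eligible_cell_gives_missing(self):
        ann = make_annotation(1)
        af = single_snp_af(0.5, ann)
        ref = reference_from_cells([("rs1", "AB", 0.5, 0.1, False)])
        assert np.isnan(snp_qi_nearest(af, ref).q.iloc[0, 0])

    def test_nearest_q_never_exceeds_genotype_q_at_equal_sigma(self):
        # with a common sigma, the nearest mean minimizes |lam - mu| by
        # construction, hence q2 <= q1 wherever both are defined
        sigma = 0.07
        mu = np.array([[0.93, 0.5, 0.07]])
        sig = np.full((1, 3), sigma)
        lams = np.linspace(0, 1, 501)[None, :]
        q2 = nearest_mean_q(lams, mu, sig)
        for g in range(3):
            q1 = np.abs(lams - mu[0, g]) / sigma
            assert (q2 <= q1 + 1e-12).all()


class TestArraySummaries:
    def test_constant_vector_is_fixed_point_of_all_summaries(self):
        x = np.full(100, 3.7)
        for kind in ("winsorized_mean", "median", "trimmed_mean"):
            assert summarize(x, 0.95, kind) == pytest.approx(3.7)

    def test_median_small_example(self):
        assert summarize(np.array([1.0, 2.0, 3.0]), 0.95, "median") == 2.0

    @staticmethod
    def brute_force_winsorized(values, rho):
        x = np.sort(np.asarray(values, dtype=float))
        n = len(x)
        # type-7 quantile: linear interpolation at h = (n-1) * rho
        h = (n - 1) * rho
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        cap = x[lo] + (h - lo) * (x[hi] - x[lo])
        return np.mean([min(v, cap) for v in x]), cap

    @given(
        values=arrays(
            np.float64,
            st.integers(10, 200),
            elements=st.floats(0, 50, allow_nan=False),
        ),
        rho=st.sampled_from([0.9, 0.95, 0.975, 0.99]),
    )
    @settings(max_examples=200, deadline=None)
    def test_winsorized_mean_matches_sort_based_oracle(self, values, rho):
        expected, _ = self.brute_force_winsorized(values, rho)
        assert winsorized_mean(values, rho) == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @given(
        values=arrays(
            np.float64,
            st.integers(10, 100),
            elements=st.floats(0, 50, allow_nan=False),
        ),
        rho=st.sampled_from([0.9, 0.95, 0.99]),
    )
    @settings(max_examples=100, deadline=None)
    def test_summary_orderings(self, values, rho):
        w = winsorized_mean(values, rho)
        assert w <= np.mean(values) + 1e-12
        assert trimmed_mean(values, rho) <= w + 1e-12
        assert winsorized_mean(values, 0.9) <= winsorized_mean(values, 0.99) + 1e-12


class TestArrayQi:
    def _snp_qi(self, n_snps=80, n_samples=4, seed=0):
        params = synth_population(n_snps, seed=seed)
        genotypes, af = simulate_arrays(params, n_samples, 0.0, seed=seed + 1)
        return snp_qi_nearest(af, params.to_af_reference())

    def test_scopes_and_counts(self):
        snp_qi = self._snp_qi()
        table = array_qi(snp_qi, min_snps=30)
        genome = table.genome()
        assert len(genome) == 4
        assert (genome["n_snps_used"] == 80).all()
        assert set(table.table["scope"]) == {"19", "GENOME"}

    def test_min_snps_skips_scope(self):
        snp_qi = self._snp_qi(n_snps=20)
        table = array_qi(snp_qi, min_snps=30)
        assert table.table.empty
        assert len(table.skipped) > 0

    def test_higher_spread_increases_index(self, small_population):
        ref = small_population.to_af_reference()
        qs = []
        for r in (0.0, 0.4):
            _, af = simulate_arrays(small_population, 50, r, seed=11)
            table = array_qi(snp_qi_nearest(af, ref), scopes="genome")
            qs.append(table.table["qi_value"].to_numpy())
        assert np.median(qs[1]) > np.median(qs[0])
        assert (qs[1].mean() - qs[0].mean()) > 0.05


class TestMerge:
    def _part(self, n, seed, chromosome, label, prefix):
        params = synth_population(n, seed=seed)
        params.snp_ids = [f"{prefix}{i}" for i in range(n)]
        genotypes, af = simulate_arrays(
            params, 5, 0.0, seed=seed + 1, chromosome=chromosome, array_label=label
        )
        return snp_qi_nearest(af, params.to_af_reference(chromosome=chromosome, array_label=label))

    def test_pooled_equals_concatenated_vector(self):
        p1 = self._part(60, 21, "1", "Nsp", "a")
        p2 = self._part(90, 22, "2", "Sty", "b")
        merged = merge_array_qi([p1, p2], rho=0.95)
        for _, row in merged.table.iterrows():
            pooled = np.concatenate(
                [p1.q[row["sample_id"]].to_numpy(), p2.q[row["sample_id"]].to_numpy()]
            )
            pooled = pooled[~np.isnan(pooled)]
            assert row["qi_value"] == pytest.approx(
                winsorized_mean(pooled, 0.95), rel=1e-12
            )
        assert (merged.table["n_snps_used"] == 150).all()
        assert (merged.table["array_label"] == "Merge").all()

    def test_identical_multisets_give_the_part_index(self):
        p1 = self._part(60, 31, "1", "Nsp", "a")
        # second part: same q multiset, different SNP ids/chromosome
        p2 = self._part(60, 31, "2", "Sty", "b")
        p2.q.loc[:, :] = p1.q.to_numpy()
        merged = merge_array_qi([p1, p2], rho=0.95)
        single = array_qi(p1, rho=0.95, scopes="genome")
        m = merged.table.set_index("sample_id")["qi_value"]
        s = single.table.set_index("sample_id")["qi_value"]
        assert np.allclose(m.loc[s.index], s, rtol=1e-12)

    def test_overlapping_snp_ids_rejected(self):
        p1 = self._part(60, 41, "1", "Nsp", "a")
        p2 = self._part(60, 42, "2", "Sty", "a")  # same prefix -> same ids
        with pytest.raises(InputError, match="multiple parts"):
            merge_array_qi([p1, p2])


class TestGcr:
    def test_no_missing_calls(self, toy_genotypes):
        gcr = compute_gcr(toy_genotypes)
        s2 = gcr.table[(gcr.table["sample_id"] == "s2") & (gcr.table["scope"] == "GENOME")]
        assert s2["gcr"].iloc[0] == 1.0

    def test_one_missing_among_four(self, toy_genotypes):
        gcr = compute_gcr(toy_genotypes)
        s1 = gcr.table[(gcr.table["sample_id"] == "s1") & (gcr.table["scope"] == "GENOME")]
        assert s1["gcr"].iloc[0] == 0.75

    def test_all_missing(self):
        ann = make_annotation(3)
        calls = pd.DataFrame(
            {"s1": ["NC", "NC", "NC"]}, index=ann["snp_id"]
        )
        gcr = compute_gcr(GenotypeMatrix(annotation=ann, calls=calls))
        assert (gcr.table["gcr"] == 0.0).all()
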