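"""Mutation matrices, Poisson intervals and stationary-state solving."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import power_iteration_stationary
from stopflux import mut_equilibrium as me
from stopflux import synthetic_data as sd


def random_rates(rng, k, low=0.1, high=1.0):
    R = rng.uniform(low, high, (k, k))
    np.fill_diagonal(R, 0.0)
    return R


class TestReadMutations:
    def _write(self, tmp_path, rows, header=True):
        path = tmp_path / "m.tsv"
        lines = (["Chr\tPos\tRef\tAlt"] if header else []) + [
            "\t".join(map(str, r)) for r in rows
        ]
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_consistent_rows_kept(self, tmp_path):
        ref = {"c": "ACGTACGTAC"}
        rows = [("c", i + 1, ref["c"][i], "A" if ref["c"][i] != "A" else "C")
                for i in range(5)]
        path = self._write(tmp_path, rows)
        assert len(me.read_mutations(path, ref)) == 5

    def test_mismatch_dropped_below_threshold(self, tmp_path):
        ref = {"c": "A" * 200}
        rows = [("c", i + 1, "A", "G") for i in range(199)] + [("c", 200, "T", "G")]
        records = me.read_mutations(self._write(tmp_path, rows), ref)
        assert len(records) == 199

    def test_excess_mismatch_is_hard_error(self, tmp_path):
        ref = {"c": "A" * 100}
        rows = [("c", i + 1, "T", "G") for i in range(10)]
        with pytest.raises(ValueError, match="mismatch"):
            me.read_mutations(self._write(tmp_path, rows), ref)

    def test_generator_output_has_zero_drops(self, small_bundle):
        rng = np.random.default_rng(1)
        muts = sd.sample_denovo(small_bundle.contigs, sd.DEFAULT_MUTATION_MATRIX, 2000, rng)
        import io

        buf = io.StringIO()
        muts.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        assert len(me.read_mutations(buf, small_bundle.contigs)) == 2000

    def test_local_gc_window(self, tmp_path):
        ref = {"c": "G" * 3000 + "A" + "T" * 3000}
        path = self._write(tmp_path, [("c", 3001, "A", "G")])
        (rec,) = me.read_mutations(path, ref, window=2000)
        assert abs(rec.local_gc - 1000 / 2000) < 1e-12


class TestMonoMatrix:
    def test_rate_arithmetic(self):
        muts = [me.MutationRecord("c", 1, "A", "G")] * 10
        mat = me.build_mono_matrix(muts, np.array([1000, 100, 100, 100]))
        assert mat.rate("A", "G") == 0.01

    def test_zero_count_cell(self):
        mat = me.build_mono_matrix([], np.array([10, 10, 10, 10]))
        assert mat.rate("A", "G") == 0.0
        assert mat.ci95[0, 2, 0] == 0.0

    def test_poisson_interval_matches_r_poisson_test(self):
        # R: poisson.test(10) gives (4.795389, 18.390356)
        lo, hi = me.poisson_ci(np.array([10]))
        assert abs(lo[0] - 4.795389) < 1e-4
        assert abs(hi[0] - 18.390356) < 1e-4


class TestSolveStationary:
    def test_symmetric_is_uniform(self):
        R = np.ones((4, 4)) - np.eye(4)
        assert np.abs(me.solve_stationary(R) - 0.25).max() < 1e-14

    def test_two_state_closed_form(self):
        u, v = 0.3, 0.1
        pi = me.solve_stationary(np.array([[0, u], [v, 0.0]]))
        assert np.abs(pi - [v / (u + v), u / (u + v)]).max() < 1e-14

    @pytest.mark.parametrize("k", [4, 16])
    def test_matches_power_iteration(self, k):
        rng = np.random.default_rng(17)
        for _ in range(10):
            R = random_rates(rng, k)
            assert np.abs(me.solve_stationary(R) - power_iteration_stationary(R)).max() < 1e-10

    def test_balance_residual(self):
        rng = np.random.default_rng(23)
        R = random_rates(rng, 16)
        pi = me.solve_stationary(R)
        gain = pi @ R
        loss = pi * R.sum(axis=1)
        assert np.abs(gain - loss).max() < 1e-12

    def test_reducible_chain_errors(self):
        R = np.zeros((3, 3))
        R[0, 1] = 1.0  # state 2 unreachable, state 0 transient
        with pytest.raises(ValueError, match="reducible"):
            me.solve_stationary(R)

    @settings(deadline=None, max_examples=25)
    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(5)
        R = random_rates(rng, 4)
        assert np.abs(me.solve_stationary(R) - me.solve_stationary(c * R)).max() < 1e-9


class TestStopEquilibrium:
    def _matrix(self, r_ag, r_ga):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 2] = int(r_ag * 1e6)
        counts[2, 0] = int(r_ga * 1e6)
        counts[0, 1] = counts[1, 0] = counts[3, 1] = 100  # keep other cells alive
        counts[1, 3] = counts[2, 3] = counts[3, 2] = 100
        return me.RateMatrix(states=tuple("ACGT"), counts=counts,
                             exposure=np.array([10**6] * 4))

    def test_symmetric_rates_give_thirds(self):
        eq = me.stop_equilibrium(self._matrix(0.003, 0.003))
        assert np.abs(np.array([eq.taa, eq.tga, eq.tag]) - 1 / 3).max() < 1e-12
        assert eq.residual < 1e-12

    def test_asymmetric_solution_satisfies_balance(self):
        eq = me.stop_equilibrium(self._matrix(0.002, 0.004))
        assert eq.residual < 1e-12
        assert eq.taa > eq.tga  # G->A flux dominates, TAA accumulates

    def test_elimination_choice_invariant(self):
        mats = self._matrix(0.0017, 0.0042)
        sols = [me.stop_equilibrium(mats, eliminate=s) for s in ("TAA", "TGA", "TAG")]
        for a in sols[1:]:
            assert abs(a.taa - sols[0].taa) < 1e-12
            assert abs(a.tga - sols[0].tga) < 1e-12

    def test_matches_full_stationary_solve(self):
        """Elimination solve agrees with the generic 3-state stationary solver."""
        fluxes = me.stop_fluxes_from_mono(self._matrix(0.0025, 0.0011))
        eq = me.stop_equilibrium(fluxes)
        order = ("TAA", "TGA", "TAG")
        R = np.zeros((3, 3))
        for i, a in enumerate(order):
            for j, b in enumerate(order):
                if i != j:
                    R[i, j] = fluxes[(a, b)]
        pi = me.solve_stationary(R)
        assert np.abs(pi - [eq.taa, eq.tga, eq.tag]).max() < 1e-12

    def test_zero_ag_rate_errors(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[2, 0] = 10
        mat = me.RateMatrix(states=tuple("ACGT"), counts=counts,
                            exposure=np.array([100] * 4))
        with pytest.raises(ValueError):
            me.stop_equilibrium(mat)


class TestDinucMatrix:
    def test_both_flanking_dinucleotides_counted(self):
        ref = {"c": "GCATG"}
        muts = [me.MutationRecord("c", 3, "A", "G")]
        mat = me.build_dinuc_matrix(muts, ref, ["GCATG"])
        assert mat.counts[me.DINUC_INDEX["CA"], me.DINUC_INDEX["CG"]] == 1
        assert mat.counts[me.DINUC_INDEX["AT"], me.DINUC_INDEX["GT"]] == 1
        assert mat.counts.sum() == 2

    def test_contig_start_counts_right_side_only(self):
        ref = {"c": "AT"}
        muts = [me.MutationRecord("c", 1, "A", "G")]
        mat = me.build_dinuc_matrix(muts, ref, ["AT"])
        assert mat.counts[me.DINUC_INDEX["AT"], me.DINUC_INDEX["GT"]] == 1
        assert mat.counts.sum() == 1

    def test_cpg_multiplier_recovered(self):
        """A planted 10x CpG C->T excess is recovered by the dinucleotide rates."""
        rng = np.random.default_rng(31)
        ref = {"c": sd.random_sequence(400_000, 0.5, rng)}
        muts_df = sd.sample_denovo(ref, sd.DEFAULT_MUTATION_MATRIX, 50_000, rng,
                                   context_multipliers={("CG", "T"): 10.0})
        muts = [me.MutationRecord(r.Chr, int(r.Pos), r.Ref, r.Alt)
                for r in muts_df.itertuples(index=False)]
        mat = me.build_dinuc_matrix(muts, ref, list(ref.values()))
        r_cg = mat.rate("CG", "TG")
        r_ca = mat.rate("CA", "TA")
        ratio = r_cg / r_ca
        n_cg = mat.counts[me.DINUC_INDEX["CG"], me.DINUC_INDEX["TG"]]
        n_ca = mat.counts[me.DINUC_INDEX["CA"], me.DINUC_INDEX["TA"]]
        se_log = np.sqrt(1 / n_cg + 1 / n_ca)
        assert abs(np.log(ratio) - np.log(10.0)) < 3 * se_log


class TestBinnedEquilibria:
    def test_single_bin_reproduces_global(self, small_bundle):
        rng = np.random.default_rng(3)
        muts_df = sd.sample_denovo(small_bundle.contigs, sd.DEFAULT_MUTATION_MATRIX,
                                   2000, rng)
        import io

        buf = io.StringIO()
        muts_df.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        muts = me.read_mutations(buf, small_bundle.contigs)
        df = me.binned_equilibria(muts, small_bundle.contigs, bins=1, kind="mono")
        profiles = {c: me.window_gc_profile(s, 10000) for c, s in small_bundle.contigs.items()}
        gcs = [m.local_gc for m in muts]
        expo = me._gc_matched_exposure(small_bundle.contigs, profiles, min(gcs), max(gcs), dinuc=False)
        mat = me.build_mono_matrix(muts, expo)
        assert abs(df.loc[0, "gc_star"] - me.mono_equilibrium(mat).gcstar) < 1e-12
        assert abs(df.loc[0, "tga_star"] - me.stop_equilibrium(mat).tga) < 1e-12

    def test_equal_bin_sizes(self, small_bundle):
        rng = np.random.default_rng(4)
        muts_df = sd.sample_denovo(small_bundle.contigs, sd.DEFAULT_MUTATION_MATRIX,
                                   3000, rng)
        muts = [me.MutationRecord(r.Chr, int(r.Pos), r.Ref, r.Alt, local_gc=rng.random())
                for r in muts_df.itertuples(index=False)]
        df = me.binned_equilibria(muts, small_bundle.contigs, bins=3, kind="mono")
        assert df["n_mutations"].tolist() == [1000, 1000, 1000]

    def test_too_few_mutations_error(self, small_bundle):
        with pytest.raises(ValueError):
            me.binned_equilibria([], small_bundle.contigs, bins=10)
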