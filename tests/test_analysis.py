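import numpy as np
import pytest
from scipy.stats import spearmanr

from refield.alphabet import PROTEIN
from refield.analysis import (
    ContactMap,
    MutationExperiment,
    array_energy,
    consensus_sequence,
    coupling_contact_overlap,
    energy_vs_identity,
    extreme_couplings,
    identity_to_consensus,
    predict_ddG,
    read_mutation_table,
)
from refield.errors import ValidationError
from refield.model import ModelParameters
from refield.msa import Alignment
from refield.sampler import sample_matrix
from refield.stats import statistics_from_matrix

from conftest import make_alignment, random_parameters


def stats_from_seqs(seqs):
    aln = make_alignment(seqs, pair_flag=True)
    return statistics_from_matrix(aln.to_matrix(), 21, pseudocount=0.0)


class TestConsensus:
    def test_dominant_residue_wins(self):
        seqs = ["AC", "AC", "AC", "AC", "AC", "AC", "AC", "AC", "AC", "GC"]
        stats = stats_from_seqs(seqs)
        assert consensus_sequence(stats)[0] == "A"

    def test_gap_never_wins(self):
        # gap is most frequent in column 0 but L leads among residues
        seqs = ["-C", "-C", "-C", "LC", "LC", "MC"]
        stats = stats_from_seqs(seqs)
        assert consensus_sequence(stats) == "LC"

    def test_matches_per_column_max_oracle(self, rng):
        mat = rng.integers(0, 21, size=(100, 6)).astype(np.int8)
        stats = statistics_from_matrix(mat, 21)
        cons = consensus_sequence(stats)
        for i in range(6):
            counts = np.bincount(mat[:, i], minlength=21)[:20]  # exclude gap
            best = counts.max()
            winners = {PROTEIN.symbols[a] for a in np.flatnonzero(counts == best)}
            assert cons[i] in winners
            # tie-break: earliest symbol in the alphabet
            assert cons[i] == min(winners, key=PROTEIN.index)

    def test_identical_rows_return_that_row(self):
        seqs = ["ACDE"] * 5
        stats = stats_from_seqs(seqs)
        assert consensus_sequence(stats) == "ACDE"


class TestIdentityToConsensus:
    def test_cases(self):
        assert identity_to_consensus("ACDE", "ACDE") == 1.0
        assert identity_to_consensus("ACDE", "GHIK") == 0.0
        assert identity_to_consensus("ACDE", "ACIK") == 0.5

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            identity_to_consensus("ACD", "ACDE")


class TestEnergyVsIdentity:
    def test_lambda_model_gives_negative_correlation(self):
        params = ModelParameters.zeros(L=6)
        params.lam[:] = 4.0 * (np.arange(4) / 3.0) ** 3
        mat = sample_matrix(params, 4000, thin=20, burn_in=500, seed=1)
        aln = Alignment.from_matrix(mat, pair_flag=True)
        df = energy_vs_identity(aln, params)
        rho, _ = spearmanr(df["energy"], df["pct_id_between_repeats"])
        assert rho < 0

    def test_null_model_uncorrelated(self):
        params = ModelParameters.zeros(L=6)
        mat = sample_matrix(params, 10000, thin=10, burn_in=100, seed=2)
        aln = Alignment.from_matrix(mat, pair_flag=True)
        df = energy_vs_identity(aln, params)
        # all energies are 0 under the null model; correlation is undefined/0
        assert df["energy"].abs().max() == 0.0

    def test_single_sequence(self):
        params = random_parameters(L=4, seed=1)
        aln = make_alignment(["ACDE"], pair_flag=True)
        df = energy_vs_identity(aln, params, consensus="ACDE")
        assert len(df) == 1
        assert df["pct_id_to_consensus"].iloc[0] == 1.0


class TestPredictDdG:
    def make_experiments(self, params, rng, n=20, slope=2.0, noise=0.0,
                         convention="destab_positive"):
        half = params.half
        exps = []
        for k in range(n):
            wt = PROTEIN.decode(rng.integers(0, 20, size=2 * half))
            pos = int(rng.integers(0, 2 * half))
            new = PROTEIN.symbols[int(rng.integers(0, 20))]
            while new == wt[pos]:
                new = PROTEIN.symbols[int(rng.integers(0, 20))]
            mut = f"{wt[pos]}{pos + 1}{new}"
            e_wt = array_energy(wt, params)
            chars = list(wt)
            chars[pos] = new
            e_mut = array_energy("".join(chars), params)
            de = e_mut - e_wt
            ddg_destab = de / slope + rng.normal(0, noise)
            ddg = ddg_destab if convention == "destab_positive" else -ddg_destab
            exps.append(
                MutationExperiment(
                    protein_id=f"p{k}", wt_sequence=wt, mutations=(mut,),
                    ddg=ddg, convention=convention,
                )
            )
        return exps

    def test_zero_noise_recovers_line(self, rng):
        params = random_parameters(L=8, seed=2, density=0.3)
        exps = self.make_experiments(params, rng, slope=2.0, noise=0.0)
        table, summary = predict_ddG(exps, params)
        assert summary["r_squared"] == pytest.approx(1.0, abs=1e-9)
        assert summary["slope"] == pytest.approx(2.0, rel=1e-6)

    def test_noisy_slope_within_ci(self, rng):
        params = random_parameters(L=8, seed=3, density=0.3)
        exps = self.make_experiments(params, rng, n=80, slope=1.5, noise=0.3)
        _, summary = predict_ddG(exps, params)
        assert 1.0 < summary["slope"] < 2.0

    def test_convention_flip_is_honored(self, rng):
        params = random_parameters(L=8, seed=4, density=0.3)
        exps_pos = self.make_experiments(params, rng, slope=2.0)
        exps_neg = [
            MutationExperiment(
                protein_id=e.protein_id, wt_sequence=e.wt_sequence,
                mutations=e.mutations, ddg=-e.ddg, convention="destab_negative",
            )
            for e in exps_pos
        ]
        _, s_pos = predict_ddG(exps_pos, params)
        _, s_neg = predict_ddG(exps_neg, params)
        assert s_neg["slope"] == pytest.approx(s_pos["slope"], rel=1e-9)
        assert s_neg["sign_agreement"] == s_pos["sign_agreement"]

    def test_order_invariance(self, rng):
        params = random_parameters(L=8, seed=5, density=0.3)
        exps = self.make_experiments(params, rng, n=15, noise=0.2)
        _, s1 = predict_ddG(exps, params)
        _, s2 = predict_ddG(exps[::-1], params)
        for key in ("slope", "intercept", "r_squared", "sign_agreement"):
            assert s1[key] == pytest.approx(s2[key], abs=1e-12)

    def test_excluded_rows_left_out_of_fit(self, rng):
        params = random_parameters(L=8, seed=6, density=0.3)
        exps = self.make_experiments(params, rng, n=10, noise=0.0)
        outlier = MutationExperiment(
            protein_id="bad", wt_sequence=exps[0].wt_sequence,
            mutations=exps[0].mutations, ddg=500.0, exclude=True,
        )
        _, s = predict_ddG(exps + [outlier], params)
        assert s["n_fit"] == 10 and s["n_total"] == 11
        assert s["r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_single_experiment_r2_undefined(self, rng):
        params = random_parameters(L=8, seed=7, density=0.3)
        exps = self.make_experiments(params, rng, n=1)
        _, s = predict_ddG(exps, params)
        assert np.isnan(s["r_squared"])

    def test_wildtype_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            MutationExperiment(
                protein_id="x", wt_sequence="ACDE", mutations=("G1H",), ddg=1.0
            )

    def test_mutation_outside_sequence_rejected(self):
        with pytest.raises(ValidationError):
            MutationExperiment(
                protein_id="x", wt_sequence="ACDE", mutations=("A9G",), ddg=1.0
            )

    def test_multi_repeat_array(self, rng):
        # arrays longer than one pair are decomposed with adjacent interfaces
        params = random_parameters(L=8, seed=8, density=0.3)
        wt = PROTEIN.decode(rng.integers(0, 20, size=12))  # 3 repeats of 4
        exp = MutationExperiment(
            protein_id="x", wt_sequence=wt, mutations=(f"{wt[5]}6{'W' if wt[5] != 'W' else 'Y'}",),
            ddg=1.0,
        )
        table, _ = predict_ddG([exp], params)
        assert np.isfinite(table["delta_E"].iloc[0])

    def test_table_round_trip(self, tmp_path, rng):
        params = random_parameters(L=8, seed=9, density=0.3)
        exps = self.make_experiments(params, rng, n=5)
        path = tmp_path / "muts.tsv"
        with open(path, "w") as fh:
            fh.write("id\twt_sequence\tmutations\tddG\tddG_sd\tconvention\texclude\n")
            for e in exps:
                fh.write(
                    f"{e.protein_id}\t{e.wt_sequence}\t{';'.join(e.mutations)}"
                    f"\t{e.ddg}\t0.1\t{e.convention}\t0\n"
                )
        back = read_mutation_table(path)
        assert [e.protein_id for e in back] == [e.protein_id for e in exps]
        assert [e.ddg for e in back] == pytest.approx([e.ddg for e in exps])


class TestExtremeCouplings:
    def test_single_large_coupling(self):
        params = ModelParameters.zeros(L=6)
        params.J[2, 4, 3, 5] = 5.0
        ext = extreme_couplings(params, top_k=1, bottom_k=0)
        assert ext == [(2, 4, 1, "top")]

    def test_k_larger_than_nonzero_count(self):
        params = ModelParameters.zeros(L=6)
        params.J[0, 1, 0, 0] = 1.0
        params.J[2, 3, 1, 1] = -1.0
        ext = extreme_couplings(params, top_k=100, bottom_k=100)
        tops = [e for e in ext if e[3] == "top"]
        assert sum(n for _, _, n, _ in tops) == 2  # no padding

    def test_matches_full_sort_oracle(self, rng):
        params = random_parameters(L=6, seed=10, density=0.02)
        k = 30
        ext = extreme_couplings(params, top_k=k, bottom_k=k)
        i, j, a, b = np.nonzero(params.J)
        vals = params.J[i, j, a, b]
        order = np.argsort(vals)
        top_pairs = {}
        for idx in order[::-1][:k]:
            key = (int(i[idx]), int(j[idx]))
            top_pairs[key] = top_pairs.get(key, 0) + 1
        got_top = {(e[0], e[1]): e[2] for e in ext if e[3] == "top"}
        assert got_top == top_pairs


class TestCouplingContactOverlap:
    def make_cmap(self, L, contacts):
        m = np.zeros((L, L), dtype=int)
        for i, j in contacts:
            m[i, j] = m[j, i] = 1
        return ContactMap(m)

    def test_all_on_contacts(self):
        cmap = self.make_cmap(6, [(0, 1), (2, 4)])
        ext = [(0, 1, 3, "top"), (2, 4, 1, "top")]
        assert coupling_contact_overlap(ext, cmap, repeat_offset=3) == 1.0

    def test_none_on_contacts(self):
        cmap = self.make_cmap(6, [(0, 1)])
        ext = [(0, 2, 1, "top")]
        assert coupling_contact_overlap(ext, cmap, repeat_offset=3) == 0.0

    def test_equivalent_positions_count_as_hits(self):
        cmap = self.make_cmap(6, [])
        ext = [(1, 4, 1, "top")]  # j = i + L/2
        assert coupling_contact_overlap(ext, cmap, repeat_offset=3) == 1.0

    def test_random_pairs_match_contact_density(self, rng):
        L = 20
        iu, ju = np.triu_indices(L, k=1)
        mask = rng.random(len(iu)) < 0.3
        cmap = self.make_cmap(L, list(zip(iu[mask], ju[mask])))
        # exclude equivalent-position pairs so the null is the density itself
        pick = rng.choice(len(iu), size=150, replace=False)
        pairs = [
            (int(iu[k]), int(ju[k]), 1, "top")
            for k in pick
            if ju[k] - iu[k] != L // 2
        ]
        overlap = coupling_contact_overlap(pairs, cmap, repeat_offset=L // 2)
        density = cmap.matrix[iu, ju].mean()
        se = np.sqrt(density * (1 - density) / len(pairs))
        assert abs(overlap - density) < 4 * se

    def test_asymmetric_map_rejected(self):
        m = np.zeros((4, 4), dtype=int)
        m[0, 1] = 1
        with pytest.raises(ValidationError):
            ContactMap(m)

    def test_read_plain_text(self, tmp_path):
        p = tmp_path / "cmap.txt"
        p.write_text("0 1\n1 0\n")
        cmap = ContactMap.read(p)
        assert cmap.width == 2
        assert cmap.matrix[0, 1] == 1
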