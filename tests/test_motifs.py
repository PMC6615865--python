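"""Promoter windows, the collapsed ZOOPS Gibbs sampler and PWM statistics."""

import numpy as np
import pandas as pd
import pytest
from itertools import product
from scipy.special import gammaln
from sklearn.metrics import roc_auc_score

from scsda import simulate_promoters
from scsda.motifs import (
    PWM,
    GibbsMotifSampler,
    PromoterSet,
    _encode,
    collapsed_gibbs_chain,
    cpg_pseudo_motif,
    extract_promoter_windows,
    filter_masked,
    motif_loading_association,
    pwm_summaries,
    scan_fixed_pwm,
)

GENOME = {"chr1": "ACGT" * 1000}


def tss_row(chrom, start, end, gene, strand):
    return pd.DataFrame(
        [(chrom, start, end, gene, 0, strand)],
        columns=["chrom", "start", "end", "gene", "score", "strand"],
    )


class TestPromoterWindows:
    def test_centered_window_plus_strand(self):
        pset = extract_promoter_windows(
            tss_row("chr1", 1000, 1500, "g", "+"), GENOME, "cent300"
        )
        assert pset.sequences[0] == GENOME["chr1"][850:1150]

    def test_upstream_minus_strand_reverse_complemented(self):
        genome = {"chr1": "A" * 50 + "CCGG" + "A" * 50}
        # gene on '-' with TSS at position 53 (end-1): upstream = [54, 54+4)
        pset = extract_promoter_windows(
            tss_row("chr1", 10, 54, "g", "-"), genome, "up4"
        )
        forward = genome["chr1"][54:58]  # AAAA
        assert pset.sequences[0] == "TTTT"[: len(forward)].replace("T", "T")
        assert pset.sequences[0] == "TTTT"

    def test_minus_strand_window_is_revcomp_of_genomic(self):
        genome = {"chr1": "ACGTACGTACGTACGTACGT"}
        pset = extract_promoter_windows(
            tss_row("chr1", 0, 10, "g", "-"), genome, "up6"
        )
        genomic = genome["chr1"][10:16]
        rc = genomic.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert pset.sequences[0] == rc

    def test_window_truncated_at_contig_start(self):
        with pytest.warns(UserWarning, match="truncated"):
            pset = extract_promoter_windows(
                tss_row("chr1", 50, 400, "g", "+"), GENOME, "up150"
            )
        assert len(pset.sequences[0]) == 50
        assert pset.truncated[0]

    def test_unknown_window_spec(self):
        with pytest.raises(ValueError):
            extract_promoter_windows(
                tss_row("chr1", 100, 200, "g", "+"), GENOME, "sideways100"
            )


class TestFilterMasked:
    def test_strictly_greater_than_threshold_removed(self):
        seqs = PromoterSet(
            gene_ids=["a", "b", "c"],
            sequences=["A" * 89 + "N" * 11, "A" * 90 + "N" * 10, "A" * 100],
            window="w",
            masked_fraction=np.array([0.11, 0.10, 0.0]),
        )
        out = filter_masked(seqs, 0.10)
        assert out.gene_ids == ["b", "c"]

    def test_all_removed_is_an_error(self):
        seqs = PromoterSet(["a"], ["N" * 100], "w", np.array([1.0]))
        with pytest.raises(ValueError):
            filter_masked(seqs)


class TestGibbsSampler:
    def test_deterministic_given_seed(self):
        pwm = PWM.from_consensus("ACGTTG", match=0.9)
        pset, _ = simulate_promoters([(pwm, 0.7)], n_seq=30, length=60, seed=0)
        a = GibbsMotifSampler(n_restarts=2, max_iter=120, random_state=4).fit(pset)
        b = GibbsMotifSampler(n_restarts=2, max_iter=120, random_state=4).fit(pset)
        np.testing.assert_array_equal(a.trace_, b.trace_)
        np.testing.assert_array_equal(a.pwm_.probs, b.pwm_.probs)

    def test_planted_motif_recovered(self, planted_motif_instance):
        inst = planted_motif_instance
        rec = inst["sampler"].pwm_.probs
        tru = inst["pwm"].probs
        best = -1.0
        for off in range(-(rec.shape[0] - 1), tru.shape[0]):
            lo_r, lo_t = max(0, -off), max(0, off)
            n = min(rec.shape[0] - lo_r, tru.shape[0] - lo_t)
            if n < 4:
                continue
            rs = [
                np.corrcoef(rec[lo_r + i], tru[lo_t + i])[0, 1] for i in range(n)
            ]
            best = max(best, float(np.nanmean(rs)))
        assert best >= 0.8

    def test_presence_posterior_discriminates(self, planted_motif_instance):
        inst = planted_motif_instance
        auroc = roc_auc_score(
            inst["planted"], inst["sampler"].presence_posterior_
        )
        assert auroc >= 0.9

    def test_background_run_less_informative_than_planted(
        self, planted_motif_instance
    ):
        pset, _ = simulate_promoters([], n_seq=60, length=120, seed=9)
        null = GibbsMotifSampler(n_restarts=3, max_iter=200, random_state=0).fit(pset)
        ic_null, _, _ = pwm_summaries(null.pwm_)
        ic_planted, _, _ = pwm_summaries(planted_motif_instance["sampler"].pwm_)
        per_col_null = ic_null / null.pwm_.length
        per_col_planted = ic_planted / planted_motif_instance["sampler"].pwm_.length
        assert per_col_null < per_col_planted

    def test_recovery_degrades_with_planting_probability(self):
        pwm = PWM.from_consensus("TGACGTCA", match=0.95)
        aurocs = []
        for plant_p in (0.8, 0.5, 0.2):
            pset, truth = simulate_promoters(
                [(pwm, plant_p)], n_seq=120, length=150, seed=21
            )
            planted = np.zeros(len(pset), dtype=bool)
            planted[[pset.gene_ids.index(g) for g in truth["seq_id"]]] = True
            gs = GibbsMotifSampler(
                n_restarts=4, max_iter=400, random_state=0
            ).fit(pset)
            aurocs.append(roc_auc_score(planted, gs.presence_posterior_))
        assert aurocs[0] >= aurocs[1] - 0.03 >= aurocs[2] - 0.06

    def test_chain_matches_enumerated_posterior(self):
        """Empirical occurrence marginals over 50,000 sweeps agree with
        brute-force enumeration of the collapsed ZOOPS posterior."""
        seqs = ["ACGTACGTAC", "TTACGTTGCA", "GGGACGTAAT"]
        w, alpha, pi = 3, 0.5, 0.5
        bg = np.full(4, 0.25)
        codes = _encode(seqs)
        positions = [len(s) - w + 1 for s in seqs]

        def log_weight(z):
            lw = 0.0
            counts = np.zeros((w, 4))
            for i, zi in enumerate(z):
                if zi < 0:
                    lw += np.log(1 - pi)
                else:
                    lw += np.log(pi) - np.log(positions[i])
                    site = codes[i][zi : zi + w]
                    for j, b in enumerate(site):
                        counts[j, b] += 1
                        lw -= np.log(bg[b])
            for j in range(w):
                lw += gammaln(4 * alpha) - gammaln(4 * alpha + counts[j].sum())
                lw += sum(
                    gammaln(alpha + counts[j, b]) - gammaln(alpha)
                    for b in range(4)
                )
            return lw

        states = list(product(*[[-1] + list(range(p)) for p in positions]))
        lws = np.array([log_weight(z) for z in states])
        pr = np.exp(lws - lws.max())
        pr /= pr.sum()
        exact = {i: {} for i in range(3)}
        for z, p in zip(states, pr):
            for i in range(3):
                exact[i][z[i]] = exact[i].get(z[i], 0.0) + p

        _, zs = collapsed_gibbs_chain(
            seqs, width=w, n_sweeps=50_000, presence_prior=pi,
            pseudocount=alpha, seed=3, background=bg, record_states=True,
        )
        zs = np.asarray(zs)
        for i in range(3):
            for v, p_exact in exact[i].items():
                assert float(np.mean(zs[:, i] == v)) == pytest.approx(
                    p_exact, abs=0.02
                )

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            GibbsMotifSampler().fit(["ACGTACGTAC"] * 5)


class TestScanFixedPWM:
    def test_consensus_sequences_score_high(self):
        pwm = PWM.from_consensus("TTGACATG", match=0.97)
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 100)) for _ in range(40)]
        carriers = range(10)
        for i in carriers:
            seqs[i] = seqs[i][:40] + "TTGACATG" + seqs[i][48:]
        post = scan_fixed_pwm(seqs, pwm)
        assert np.all(post[:10] > 0.95)
        assert np.median(post[10:]) < 0.1

    def test_background_sequences_below_prior(self):
        pwm = PWM.from_consensus("TTGACATG", match=0.97)
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGT"), 100)) for _ in range(50)]
        post, trace = scan_fixed_pwm(seqs, pwm, return_trace=True)
        assert np.median(post) < trace[-1] + 0.05
        assert trace[-1] < 0.2

    def test_uniform_pwm_uninformative(self):
        pwm = PWM(np.full((6, 4), 0.25))
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(30)]
        post = scan_fixed_pwm(
            seqs, pwm, presence_prior=0.5, background=np.full(4, 0.25)
        )
        np.testing.assert_allclose(post, 0.5, atol=1e-9)


class TestAssociation:
    def test_affine_relationship_perfect(self):
        x = np.linspace(0, 1, 50)
        r, z, p = motif_loading_association(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert z > 10 and p < 1e-10

    def test_anticorrelation_negative_z(self):
        x = np.linspace(0, 1, 50)
        r, z, _ = motif_loading_association(x, -x + np.sin(x) * 0.01)
        assert r < -0.99 and z < 0

    def test_permutation_null_z_is_standard_normal(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        zs = [
            motif_loading_association(x, rng.permutation(y))[1]
            for _ in range(1000)
        ]
        assert np.mean(zs) == pytest.approx(0.0, abs=0.12)
        assert np.std(zs) == pytest.approx(1.0, abs=0.12)

    def test_zero_variance_recorded_missing(self):
        r, z, p = motif_loading_association(np.ones(20), np.arange(20.0))
        assert np.isnan(r) and np.isnan(z)


class TestPWMStatistics:
    @pytest.mark.parametrize(
        "seq,count", [("ACGCGT", 2), ("CCCC", 0), ("CGCG", 2), ("acgcgt", 2)]
    )
    def test_cpg_counts(self, seq, count):
        assert cpg_pseudo_motif([seq])[0] == count

    def test_uniform_pwm_zero_information(self):
        ic, cpg, flag = pwm_summaries(PWM(np.full((7, 4), 0.25)))
        assert ic == pytest.approx(0.0, abs=1e-12)
        assert not flag

    def test_deterministic_column_two_bits(self):
        pwm = PWM.from_consensus("ACGT")
        ic, _, _ = pwm_summaries(pwm)
        assert ic == pytest.approx(8.0)

    def test_cg_dinucleotide_probability(self):
        probs = np.array([[0, 1.0, 0, 0], [0, 0, 1.0, 0]])
        ic, cpg, flag = pwm_summaries(PWM(probs))
        assert cpg == pytest.approx(1.0)
        assert flag

    def test_single_column_has_no_cpg(self):
        _, cpg, flag = pwm_summaries(PWM(np.array([[0.25, 0.25, 0.25, 0.25]])))
        assert cpg == 0.0 and not flag

    def test_pwm_rows_validated(self):
        with pytest.raises(ValueError):
            PWM(np.array([[0.5, 0.5, 0.5, 0.5]]))
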