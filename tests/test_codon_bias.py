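"""Tests for codon counting, ENC′, ΔENC′, P and S.

The ENC′ checks compare against an independent brute-force implementation
of the background-corrected homozygosity, written directly from the
chi-square definition with explicit loops.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maxgrowth.codon_bias import (
    CodonCounts,
    S_PAIRS,
    UndefinedIndexError,
    concatenated_indices,
    count_codons,
    delta_enc_prime,
    enc_prime,
    gene_level_indices,
    p_optimal,
    s_index,
)
from maxgrowth.genetic_code import sense_codons, synonymous_families
from maxgrowth.seq_io import GeneRecord, GeneSetPartition


def brute_force_enc_prime(counts, background):
    """Independent step-by-step ENC′: chi-square homozygosity per family,
    class averages, Wright's combination 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6."""
    bg = dict(zip("ACGT", background))
    per_class = {2: [], 3: [], 4: [], 6: []}
    for _, codons in synonymous_families(11):
        k = len(codons)
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        e_raw = [bg[c[0]] * bg[c[1]] * bg[c[2]] for c in codons]
        e = [x / sum(e_raw) for x in e_raw]
        chi2 = 0.0
        for c, ei in zip(codons, e):
            p = counts.get(c, 0) / n
            chi2 += (p - ei) ** 2 / ei
        chi2 *= n
        f = (chi2 + n - k) / (k * (n - 1))
        per_class[k].append(max(f, 1e-12))
    means = {k: sum(v) / len(v) for k, v in per_class.items() if v}
    for k in (2, 3, 4, 6):
        if k not in means:
            if k == 3 and 2 in means and 4 in means:
                means[3] = (means[2] + means[4]) / 2
            else:
                means[k] = sum(means.values()) / len(means)
    enc = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(max(enc, 20.0), 61.0)


def _cc(counts, background=(0.25, 0.25, 0.25, 0.25)):
    return CodonCounts(
        counts=dict(counts), background=np.asarray(background, float),
        n_codons=sum(counts.values()),
    )


class TestCountCodons:
    def test_single_gene_excludes_stop(self):
        cc = count_codons([GeneRecord(id="g", seq="ATGAAATAA")], concatenate=True)
        assert cc.counts == {"ATG": 1, "AAA": 1}
        assert cc.n_codons == 2

    def test_pooled_equals_sum_of_per_gene(self):
        genes = [
            GeneRecord(id="a", seq="ATGGCTGCCTAA"),
            GeneRecord(id="b", seq="ATGTTTTTCTAA"),
        ]
        pooled = count_codons(genes, concatenate=True)
        per = count_codons(genes, concatenate=False)
        summed = {}
        for cc in per:
            for c, n in cc.counts.items():
                summed[c] = summed.get(c, 0) + n
        assert pooled.counts == summed

    def test_codon_with_n_skipped(self):
        cc = count_codons([GeneRecord(id="g", seq="ATGANAAAATAA")], concatenate=True)
        assert cc.counts == {"ATG": 1, "AAA": 1}
        assert cc.n_codons == 2

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            count_codons([])


class TestEncPrime:
    def test_maximal_bias_floor(self):
        counts = {codons[0]: 50 for _, codons in synonymous_families(11)}
        counts.update({"ATG": 50, "TGG": 50})
        assert enc_prime(_cc(counts)) == pytest.approx(20.0, abs=1e-12)

    def test_background_matching_usage_hits_cap(self):
        counts = {c: 100 for c in sense_codons(11)}
        assert enc_prime(_cc(counts)) == pytest.approx(61.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        counts = {c: int(rng.integers(0, 40)) for c in sense_codons(11)}
        bg = rng.dirichlet(np.ones(4) * 5)
        cc = _cc(counts, bg)
        assert enc_prime(cc) == pytest.approx(
            brute_force_enc_prime(counts, bg), abs=1e-9
        )

    def test_three_amino_acid_toy_table_matches_brute_force(self):
        # only Phe (2-fold), Ile (3-fold) and Ala (4-fold) observed
        counts = {"TTT": 7, "TTC": 3, "ATT": 5, "ATC": 4, "ATA": 1,
                  "GCT": 6, "GCC": 2, "GCA": 1, "GCG": 1}
        bg = (0.3, 0.2, 0.2, 0.3)
        assert enc_prime(_cc(counts, bg)) == pytest.approx(
            brute_force_enc_prime(counts, bg), abs=1e-9
        )

    def test_two_missing_classes_undefined(self):
        counts = {"TTT": 5, "TTC": 5}  # only a 2-fold family observed
        with pytest.raises(UndefinedIndexError):
            enc_prime(_cc(counts))

    def test_stable_under_gene_set_duplication(self, biased_partition):
        # duplicating every gene only perturbs the finite-sample correction
        # terms, which are negligible at genome-scale counts
        doubled = GeneSetPartition(
            heg=[GeneRecord(id=g.id + suffix, seq=g.seq)
                 for g in biased_partition.heg for suffix in ("", "_dup")],
            background=[GeneRecord(id=g.id + suffix, seq=g.seq)
                        for g in biased_partition.background for suffix in ("", "_dup")],
        )
        a = concatenated_indices(biased_partition)
        b = concatenated_indices(doubled)
        assert b.enc_all == pytest.approx(a.enc_all, abs=0.2)
        assert b.enc_heg == pytest.approx(a.enc_heg, abs=0.2)
        assert b.s == pytest.approx(a.s, abs=1e-9)


class TestDeltaAndP:
    @pytest.mark.parametrize(
        "enc_all,enc_heg,expected",
        [(50.0, 50.0, 0.0), (50.0, 35.0, 0.30), (61.0, 20.0, 41 / 61)],
    )
    def test_delta_enc_values(self, enc_all, enc_heg, expected):
        assert delta_enc_prime(enc_all, enc_heg) == pytest.approx(expected)

    def test_delta_enc_range_check(self):
        with pytest.raises(ValueError):
            delta_enc_prime(65.0, 30.0)

    def test_p_optimal_values_and_absence(self):
        cc = _cc({"TTC": 8, "TTT": 2, "ATC": 3, "ATT": 3, "TAC": 1, "TAT": 1})
        p = p_optimal(cc)
        assert p["Phe"] == pytest.approx(0.8)
        assert p["Ile"] == pytest.approx(0.5)
        assert p["Asn"] is None


class TestSIndex:
    def test_no_signal_gives_zero(self):
        p = {aa: 0.5 for aa in S_PAIRS}
        w = {aa: 10 for aa in S_PAIRS}
        _, s = s_index(p, p, w)
        assert s == pytest.approx(0.0)

    def test_single_amino_acid_log_odds(self):
        comp, s = s_index({"Phe": 0.8}, {"Phe": 0.5}, {"Phe": 12})
        assert s == pytest.approx(np.log(4.0))
        assert comp["Phe"] == pytest.approx(np.log(4.0))

    def test_weighted_mean(self):
        e = np.e
        p_heg = {"Phe": e / (1 + e), "Ile": 0.5}  # S = 1 and 0 against 0.5
        p_all = {"Phe": 0.5, "Ile": 0.5}
        _, s = s_index(p_heg, p_all, {"Phe": 30, "Ile": 10})
        assert s == pytest.approx(0.75)

    def test_all_degenerate_raises(self):
        with pytest.raises(UndefinedIndexError):
            s_index({"Phe": 1.0}, {"Phe": 0.5}, {"Phe": 5})


class TestModes:
    def test_single_gene_concatenated_equals_gene_averaged(self):
        rng = np.random.default_rng(21)
        codons = [c for c in sense_codons(11)]
        body = "".join(rng.choice(codons) for _ in range(400))
        gene = GeneRecord(id="g", seq="ATG" + body + "TAA")
        part = GeneSetPartition(
            heg=[GeneRecord(id="h", seq=gene.seq)], background=[gene]
        )
        a = concatenated_indices(part)
        b = gene_level_indices(part)
        assert a.enc_all == pytest.approx(b.enc_all, abs=1e-9)
        assert a.delta_enc == pytest.approx(b.delta_enc, abs=1e-9)
        assert a.s == pytest.approx(b.s, abs=1e-9)

    def test_gene_average_of_enc_means(self):
        # mean ENC' semantics: Δa formed from per-set means of per-gene ENC'
        rng = np.random.default_rng(22)
        codons = [c for c in sense_codons(11)]
        genes = [
            GeneRecord(id=f"g{i}", seq="ATG" + "".join(rng.choice(codons) for _ in range(300)) + "TAA")
            for i in range(4)
        ]
        part = GeneSetPartition(heg=genes[:2], background=genes[2:])
        from maxgrowth.codon_bias import per_gene_stats

        idx = gene_level_indices(part)
        ea = np.nanmean(per_gene_stats(part.background).enc)
        eh = np.nanmean(per_gene_stats(part.heg).enc)
        assert idx.delta_enc == pytest.approx((ea - eh) / ea, abs=1e-12)

    def test_mixed_species_gene_average_exceeds_concatenated(self):
        """Two species with opposite preferred codons: pooling washes the
        signal out, gene-level averaging keeps it."""
        def heg_gene(gid, c_ending):
            pairs = [(c1 if c_ending else c2) for c1, c2 in S_PAIRS.values()]
            fourfold = "GCC" if c_ending else "GCA"
            twofold_extra = "GAA" if c_ending else "GAG"
            body = ("".join(pairs) + fourfold + twofold_extra) * 30
            return GeneRecord(id=gid, seq="ATG" + body + "TAA")

        def bg_gene(gid, seed):
            rng = np.random.default_rng(seed)
            codons = [c for c in sense_codons(11)]
            return GeneRecord(
                id=gid, seq="ATG" + "".join(rng.choice(codons) for _ in range(300)) + "TAA"
            )

        part = GeneSetPartition(
            heg=[heg_gene("hA", True), heg_gene("hB", False)],
            background=[bg_gene(f"b{i}", 100 + i) for i in range(6)],
        )
        conc = concatenated_indices(part)
        avg = gene_level_indices(part)
        assert avg.delta_enc > conc.delta_enc

    def test_permutation_invariance(self, biased_partition):
        part = biased_partition
        flipped = GeneSetPartition(
            heg=list(reversed(part.heg)),
            background=list(reversed(part.background)),
            selection_method=part.selection_method,
        )
        a = concatenated_indices(part)
        b = concatenated_indices(flipped)
        assert a.enc_all == pytest.approx(b.enc_all, abs=1e-12)
        assert a.s == pytest.approx(b.s, abs=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    counts=st.dictionaries(
        st.sampled_from(sense_codons(11)), st.integers(0, 50), min_size=20
    )
)
def test_enc_prime_within_bounds_whenever_defined(counts):
    cc = CodonCounts(
        counts=counts, background=np.full(4, 0.25), n_codons=sum(counts.values())
    )
    try:
        enc = enc_prime(cc)
    except UndefinedIndexError:
        return
    assert 20.0 <= enc <= 61.0
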