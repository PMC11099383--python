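import itertools

import numpy as np
import pandas as pd
import pytest

from gpcraxes.coregulation import (
    build_code_matrix,
    cluster_pairs,
    code_score,
    concordance_prevalence,
    correlation_calls,
    mutation_axis_association,
    similarity_profiles,
)


def code_score_oracle(lfc_r, padj_r, lfc_p, padj_p):
    """Direct transcription of the published three-case scoring rule."""
    both_above = abs(lfc_r) > 1 and abs(lfc_p) > 1
    same_dir = lfc_r * lfc_p > 0
    sig_r, sig_p = padj_r < 0.01, padj_p < 0.01
    if both_above and same_dir and sig_r and sig_p:
        return 2 if lfc_r > 0 else -2
    if both_above and same_dir and (sig_r or sig_p):
        return 1 if lfc_r > 0 else -1
    return 0


class TestCodeScore:
    @pytest.mark.parametrize(
        "de_r, de_p, expected",
        [
            ((1.5, 0.001), (2.0, 0.004), 2),
            ((1.5, 0.001), (1.2, 0.20), 1),
            ((1.5, 0.001), (-1.5, 0.001), 0),  # anti-regulation
            ((0.5, 0.001), (2.0, 0.001), 0),  # below fold-change threshold
            ((-1.5, 0.001), (-2.0, 0.001), -2),
            ((-1.5, 0.5), (-2.0, 0.001), -1),
            ((1.5, 0.5), (2.0, 0.5), 0),  # neither significant
            ((float("nan"), 0.001), (2.0, 0.001), 0),  # missing scores zero
        ],
    )
    def test_documented_cases(self, de_r, de_p, expected):
        assert code_score(de_r, de_p) == expected

    def test_exhaustive_enumeration_matches_oracle(self):
        """All sign x magnitude x significance combinations per gene."""
        per_gene = [
            s * m for s, m in itertools.product((-1, 0, 1), (0.5, 1.5))
        ]
        padjs = (0.001, 0.5)
        cases = list(itertools.product(per_gene, padjs))
        assert len(cases) == 12
        for (l1, p1), (l2, p2) in itertools.product(cases, cases):
            assert code_score((l1, p1), (l2, p2)) == code_score_oracle(l1, p1, l2, p2), (
                l1, p1, l2, p2,
            )

    def test_symmetric_and_odd(self):
        for (l1, p1), (l2, p2) in itertools.product(
            [(1.5, 0.001), (-1.2, 0.1), (0.4, 0.001)], repeat=2
        ):
            assert code_score((l1, p1), (l2, p2)) == code_score((l2, p2), (l1, p1))
            assert code_score((-l1, p1), (-l2, p2)) == -code_score((l1, p1), (l2, p2))


class TestBuildCodeMatrix:
    PAIRS = [("R1", "L1", "ligand"), ("R2", "L2", "ligand"), ("R2", "E1", "enzyme")]

    def test_scores_and_recurrence_filter(self, de_tables):
        full, filtered = build_code_matrix(de_tables, self.PAIRS)
        # R1-L1: +2 in S1, +1 in S2 (L1 padj 0.05), 0 elsewhere -> 2/4 = 50% kept
        assert full.loc[("R1", "L1", "ligand")].tolist() == [2, 1, 0, 0]
        assert ("R1", "L1", "ligand") in filtered.index

    def test_recurrence_boundary_inclusive(self, de_tables):
        # a pair nonzero in exactly 1 of 4 subtypes (25%) is retained
        tables = {s: t.copy() for s, t in de_tables.items()}
        tables["S2"].loc[tables["S2"]["gene"] == "L1", "lfc"] = 0.0
        full, filtered = build_code_matrix(tables, [("R1", "L1", "ligand")])
        assert (full.loc[("R1", "L1", "ligand")] != 0).sum() == 1
        assert len(filtered) == 1

    def test_below_boundary_dropped(self, de_tables):
        tables = {s: t.copy() for s, t in de_tables.items()}
        tables["S2"].loc[tables["S2"]["gene"] == "L1", "lfc"] = 0.0
        _, filtered = build_code_matrix(tables, [("R1", "L1", "ligand")], recurrence_fraction=0.3)
        assert len(filtered) == 0

    def test_missing_gene_scores_zero(self, de_tables):
        full, _ = build_code_matrix(de_tables, [("R1", "ABSENT", "ligand")])
        assert (full.loc[("R1", "ABSENT", "ligand")] == 0).all()

    def test_filter_monotone_in_recurrence(self, de_tables):
        sizes = []
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            _, filtered = build_code_matrix(de_tables, self.PAIRS, recurrence_fraction=frac)
            sizes.append(len(filtered))
        assert sizes == sorted(sizes, reverse=True)


def ward_oracle(X, n_clusters=2):
    """Brute-force agglomeration with the Lance-Williams Ward update."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    clusters = {i: [i] for i in range(n)}
    # squared Euclidean distances scaled per Ward's objective
    d = {}
    for i, j in itertools.combinations(range(n), 2):
        d[(i, j)] = float(np.sum((X[i] - X[j]) ** 2))
    sizes = {i: 1 for i in range(n)}
    next_id = n
    while len(clusters) > n_clusters:
        (a, b), _ = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        na, nb = sizes[a], sizes[b]
        merged = clusters.pop(a) + clusters.pop(b)
        new = {}
        for (i, j), val in d.items():
            if a in (i, j) or b in (i, j):
                continue
            new[(i, j)] = val
        for k in clusters:
            nk = sizes[k]
            dak = d[tuple(sorted((a, k)))]
            dbk = d[tuple(sorted((b, k)))]
            dab = d[tuple(sorted((a, b)))]
            val = (
                (na + nk) * dak + (nb + nk) * dbk - nk * dab
            ) / (na + nb + nk)
            new[tuple(sorted((k, next_id)))] = val
        clusters[next_id] = merged
        sizes[next_id] = na + nb
        d = new
        next_id += 1
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(sorted(clusters.values(), key=min), start=1):
        labels[members] = lab
    return labels


def partitions_equal(a, b):
    return {frozenset(np.where(np.asarray(a) == l)[0]) for l in set(a)} == {
        frozenset(np.where(np.asarray(b) == l)[0]) for l in set(b)
    }


class TestClusterPairs:
    def _matrix(self, rows):
        idx = pd.MultiIndex.from_tuples(
            [(f"R{i}", f"L{i}", "ligand") for i in range(len(rows))],
            names=["receptor", "partner", "partner_kind"],
        )
        return pd.DataFrame(rows, index=idx)

    def test_perfectly_separated(self):
        rows = [[2] * 8] * 10 + [[-2] * 8] * 10
        labels, _ = cluster_pairs(self._matrix(rows))
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_identical_rows_merge_at_height_zero(self):
        rows = [[1, 1], [1, 1], [5, 5]]
        _, Z = cluster_pairs(self._matrix(rows))
        assert Z[0, 2] == pytest.approx(0.0)

    def test_matches_lance_williams_oracle(self, rng):
        for n_rows in (3, 5, 8, 12):
            for _ in range(5):
                X = rng.integers(-2, 3, size=(n_rows, 8)).astype(float)
                X += rng.normal(0, 1e-6, size=X.shape)  # break exact ties
                labels, _ = cluster_pairs(self._matrix(X))
                assert partitions_equal(labels, ward_oracle(X))

    def test_too_few_rows(self):
        from gpcraxes.errors import DegenerateInputError

        with pytest.raises(DegenerateInputError):
            cluster_pairs(self._matrix([[1, 2]]), n_clusters=2)


class TestSimilarityProfiles:
    def _matrix(self, rows, receptor="R1"):
        idx = pd.MultiIndex.from_tuples(
            [(receptor, f"L{i}", "ligand") for i in range(len(rows))],
            names=["receptor", "partner", "partner_kind"],
        )
        return pd.DataFrame(rows, index=idx, columns=["S1", "S2"])

    def test_identical_profiles_zero_distance(self):
        out = similarity_profiles(self._matrix([[2, 2], [2, 2]]))
        assert out.loc["R1", "ligand_wise"] == 0.0

    def test_forced_arithmetic_sqrt32(self):
        out = similarity_profiles(self._matrix([[2, 2], [-2, -2]]))
        assert out.loc["R1", "ligand_wise"] == pytest.approx(np.sqrt(32))

    def test_three_ligands_mean_of_pairwise(self):
        rows = [[2, 0], [0, 2], [-2, -2]]
        expected = np.mean(
            [
                np.linalg.norm(np.array(a) - np.array(b))
                for a, b in itertools.combinations(rows, 2)
            ]
        )
        out = similarity_profiles(self._matrix(rows))
        assert out.loc["R1", "ligand_wise"] == pytest.approx(expected)
        assert out.loc["R1", "n_ligands"] == 3

    def test_single_ligand_zero(self):
        out = similarity_profiles(self._matrix([[2, -2]]))
        assert out.loc["R1", "ligand_wise"] == 0.0

    def test_updown_balance(self):
        out = similarity_profiles(self._matrix([[2, 2], [-2, 2]]))
        # ligand 1: 2 up, 0 down -> +2; ligand 2: 1 up, 1 down -> 0
        assert out.loc["R1", "updown_balance"] == pytest.approx(1.0)

    def test_tissue_wise_uses_per_tissue_means(self):
        m = self._matrix([[2, -2]])
        out = similarity_profiles(m, subtype_tissue={"S1": "T1", "S2": "T2"})
        # per-tissue vectors across the single ligand: [2] vs [-2] -> distance 4
        assert out.loc["R1", "tissue_wise"] == pytest.approx(4.0)


class TestCorrelationCalls:
    def _expr(self, rng, n_genes=120, n_samples=50, planted=("gA", "gB"), r=0.9):
        X = rng.normal(size=(n_genes, n_samples))
        genes = [f"g{i}" for i in range(n_genes - 2)] + list(planted)
        X[-1] = r * X[-2] + np.sqrt(1 - r**2) * rng.normal(size=n_samples)
        return pd.DataFrame(X, index=genes)

    def test_planted_pair_called(self, rng):
        expr = self._expr(rng)
        out = correlation_calls(expr, [("gA", "gB")], n_background=300, seed=1)
        assert bool(out.loc[0, "correlated"]) is True
        assert out.loc[0, "r"] > 0.7

    def test_low_r_never_called(self, rng):
        expr = self._expr(rng, r=0.15)
        out = correlation_calls(expr, [("gA", "gB")], n_background=300, seed=1)
        assert abs(out.loc[0, "r"]) < 0.4
        if abs(out.loc[0, "r"]) <= 0.25:
            assert bool(out.loc[0, "correlated"]) is False

    def test_constant_gene_flagged_missing(self, rng):
        expr = self._expr(rng)
        expr.loc["gA"] = 1.0
        out = correlation_calls(expr, [("gA", "gB")], n_background=100, seed=1)
        assert np.isnan(out.loc[0, "r"]) and pd.isna(out.loc[0, "correlated"])

    def test_seeded_reproducibility(self, rng):
        expr = self._expr(rng)
        a = correlation_calls(expr, [("gA", "gB")], n_background=200, seed=5)
        b = correlation_calls(expr, [("gA", "gB")], n_background=200, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_recovery_with_null_pairs(self):
        """One true r=0.8 pair among 99 nulls: planted recovered, few false calls."""
        hits, false_rates = [], []
        for seed in range(20):
            g = np.random.default_rng(seed)
            expr = self._expr(g, n_genes=300, n_samples=50, r=0.8)
            pairs = [("gA", "gB")] + [(f"g{2 * i}", f"g{2 * i + 1}") for i in range(99)]
            out = correlation_calls(expr, pairs, n_background=500, seed=seed)
            hits.append(bool(out.loc[0, "correlated"]))
            false_rates.append(out["correlated"].iloc[1:].astype(bool).mean())
        assert np.mean(hits) >= 0.95
        assert np.mean(false_rates) <= 0.05


class TestConcordancePrevalence:
    def test_counts_and_flag(self, de_tables):
        pairs = [("R1", "L1", "ligand"), ("R2", "L2", "ligand"), ("R2", "E1", "enzyme")]
        out = concordance_prevalence(de_tables, pairs)
        # S1: R1/L1 concordant (+,+); R2/L2 concordant (-,-); R2/E1 discordant (-,+)
        assert out.loc["S1", "n_concordant"] == 2
        assert out.loc["S1", "n_discordant"] == 1
        assert bool(out.loc["S1", "prevalence_flag"]) is True

    def test_no_qualifying_pairs(self, de_tables):
        out = concordance_prevalence(de_tables, [("R3", "L1", "ligand")])
        assert out.loc["S3", "n_concordant"] == 0
        assert bool(out.loc["S3", "prevalence_flag"]) is False

    def test_planted_majority_concordant(self):
        rng = np.random.default_rng(4)
        subtypes = {}
        pairs = [(f"R{i}", f"L{i}", "ligand") for i in range(40)]
        for s in range(20):
            rows = []
            for i in range(40):
                concord = rng.random() < 0.7
                lr = rng.choice([-2.0, 2.0])
                lp = lr if concord else -lr
                rows.append((f"R{i}", lr, 0.001, 0.001))
                rows.append((f"L{i}", lp, 0.001, 0.001))
            subtypes[f"S{s}"] = pd.DataFrame(rows, columns=["gene", "lfc", "pvalue", "padj"])
        out = concordance_prevalence(subtypes, pairs)
        assert out["prevalence_flag"].sum() >= 18


class TestMutationAxisAssociation:
    def _matrix(self):
        idx = pd.MultiIndex.from_tuples(
            [(f"R{i}", f"L{i}", "ligand") for i in range(6)],
            names=["receptor", "partner", "partner_kind"],
        )
        scores = pd.DataFrame(0, index=idx, columns=["S1", "S2"])
        scores.loc[:, "S1"] = [2, 2, -2, 1, 0, 0]  # 3 axes with |score|=2
        scores.loc[:, "S2"] = [2, 2, 2, 2, 2, -2]  # 6 axes
        return scores

    def _mutations(self, gene_freqs):
        rows = []
        for subtype, freqs in gene_freqs.items():
            for gene, samples in freqs.items():
                rows += [{"gene": gene, "sample": s, "subtype": subtype} for s in samples]
        return pd.DataFrame(rows)

    def test_average_over_ranked_subtypes(self):
        muts = self._mutations(
            {"S1": {"TP53": ["a", "b", "c"]}, "S2": {"TP53": ["d", "e"]}}
        )
        out = mutation_axis_association(
            muts, {"TP53": "TSG"}, self._matrix(), subtype_samples={"S1": 10, "S2": 10}
        )
        assert out.loc[0, "gene"] == "TP53"
        assert out.loc[0, "avg_coregulated_axes"] == pytest.approx((3 + 6) / 2)

    def test_gene_never_top_k_absent(self):
        muts = self._mutations(
            {"S1": {f"G{i}": ["a", "b"] for i in range(5)} | {"RARE": ["a"]}}
        )
        genes = {f"G{i}": "oncogene" for i in range(5)} | {"RARE": "oncogene"}
        out = mutation_axis_association(muts, genes, self._matrix(), subtype_samples={"S1": 10})
        assert "RARE" not in set(out["gene"])

    def test_tie_at_rank_k_keeps_both(self):
        freqs = {f"G{i}": ["a", "b", "c"] for i in range(4)}
        freqs["T1"] = ["a", "b"]
        freqs["T2"] = ["c", "d"]
        muts = self._mutations({"S1": freqs})
        genes = {g: "oncogene" for g in freqs}
        out = mutation_axis_association(muts, genes, self._matrix(), subtype_samples={"S1": 10})
        assert {"T1", "T2"} <= set(out["gene"])

    def test_sample_counted_once_despite_multiplicity(self):
        muts = pd.DataFrame(
            [
                {"gene": "TP53", "sample": "a", "subtype": "S1"},
                {"gene": "TP53", "sample": "a", "subtype": "S1"},
                {"gene": "KRAS", "sample": "a", "subtype": "S1"},
                {"gene": "KRAS", "sample": "b", "subtype": "S1"},
            ]
        )
        out = mutation_axis_association(
            muts, {"TP53": "TSG", "KRAS": "oncogene"}, self._matrix(), subtype_samples={"S1": 4}
        )
        # KRAS mutated in 2 distinct samples, TP53 in 1
        assert set(out["gene"]) == {"TP53", "KRAS"}
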