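"""The synthetic-data generator: structure, signal and determinism."""

import io

import numpy as np
import pytest

from gopredict.data_io import read_annotations, read_fasta, read_string_links
from gopredict.ontology import parse_obo, propagate_annotations
from gopredict.synthetic import (
    SynthConfig,
    dummy_records,
    generate_annotations,
    generate_dag,
    generate_embeddings,
    generate_ppi,
    scenario,
    shuffle_edges,
    write_obo,
)
from gopredict.seeds import substream


CFG = SynthConfig(n_terms=25, dag_depth=3, n_proteins=150, seed=5)


class TestGenerateDag:
    def test_single_term_is_root_alone(self):
        dag = generate_dag(SynthConfig(n_terms=1, dag_depth=1))
        assert len(dag.terms) == 1 and len(dag.roots) == 1

    def test_layered_depth_bound(self):
        dag = generate_dag(CFG)
        root = next(iter(dag.roots))

        def depth(t):
            return 0 if not dag.parents[t] else 1 + max(map(depth, dag.parents[t]))

        assert all(depth(t) <= CFG.dag_depth for t in dag.terms)
        assert all(root in dag.ancestors(t) for t in dag.terms - {root})

    def test_same_seed_identical(self):
        a, b = generate_dag(CFG), generate_dag(CFG)
        assert a.terms == b.terms and a.parents == b.parents


class TestGenerateAnnotations:
    def test_closure_holds_for_every_protein(self):
        dag = generate_dag(CFG)
        ann = generate_annotations(dag, CFG)
        closed = propagate_annotations(dag, ann)
        assert closed.annotations == ann.annotations

    def test_within_function_jaccard_exceeds_cross(self):
        dag = generate_dag(CFG)
        ann = generate_annotations(dag, CFG)
        proteins = sorted(ann.annotations)
        rng = np.random.default_rng(0)
        within, cross = [], []
        for _ in range(2000):
            a, b = rng.choice(len(proteins), size=2, replace=False)
            pa, pb = proteins[int(a)], proteins[int(b)]
            sa, sb = ann.annotations[pa], ann.annotations[pb]
            j = len(sa & sb) / len(sa | sb)
            (within if ann.latent[pa] == ann.latent[pb] else cross).append(j)
        assert np.mean(within) > np.mean(cross)

    def test_degenerate_single_leaf_functions(self):
        cfg = SynthConfig(n_terms=6, dag_depth=2, n_proteins=20,
                          n_latent_functions=2, labels_per_protein=1.0, seed=3)
        dag = generate_dag(cfg)
        ann = generate_annotations(dag, cfg)
        for p, terms in ann.annotations.items():
            assert len(terms) >= 1


class TestGenerateEmbeddings:
    def test_zero_signal_uncorrelated_with_labels(self):
        cfg = SynthConfig(n_terms=20, dag_depth=2, n_proteins=500,
                          signal_strength=0.0, seed=9)
        dag = generate_dag(cfg)
        ann = generate_annotations(dag, cfg)
        store = generate_embeddings(ann, dag, "a", cfg)
        proteins = sorted(ann.annotations)
        X = store.batch(proteins)
        terms = sorted({t for s in ann.annotations.values() for t in s})
        y = np.array([[t in ann.annotations[p] for t in terms] for p in proteins],
                     dtype=float)
        # correlation of each embedding dim with each label column ~ 0
        Xc = (X - X.mean(0)) / (X.std(0) + 1e-12)
        keep = y.std(0) > 0
        yc = (y[:, keep] - y[:, keep].mean(0)) / y[:, keep].std(0)
        r = np.abs(Xc.T @ yc / len(proteins))
        assert r.max() < 0.2 and np.median(r) < 0.1

    def test_zero_noise_is_function_of_labels(self):
        cfg = SynthConfig(n_terms=15, dag_depth=2, n_proteins=60,
                          noise_sd=0.0, seed=4)
        dag = generate_dag(cfg)
        ann = generate_annotations(dag, cfg)
        store = generate_embeddings(ann, dag, "a", cfg)
        by_labels = {}
        for p in sorted(ann.annotations):
            key = frozenset(ann.annotations[p])
            vec = store.get(p)
            if key in by_labels:
                np.testing.assert_array_equal(by_labels[key], vec)
            by_labels[key] = vec

    def test_modalities_use_distinct_projections(self):
        dag = generate_dag(CFG)
        ann = generate_annotations(dag, CFG)
        a = generate_embeddings(ann, dag, "a", CFG)
        b = generate_embeddings(ann, dag, "b", CFG)
        p = sorted(ann.annotations)[0]
        assert not np.allclose(a.get(p), b.get(p))


class TestGeneratePpi:
    def test_full_homophily_only_within_groups(self):
        cfg = SynthConfig(n_terms=20, dag_depth=2, n_proteins=120,
                          ppi_homophily=1.0, seed=2)
        dag = generate_dag(cfg)
        ann = generate_annotations(dag, cfg)
        table = generate_ppi(ann, cfg)
        assert len(table) > 0
        for a, b, _ in table:
            assert ann.latent[a] == ann.latent[b]

    def test_half_homophily_ratio_near_one(self):
        cfg = SynthConfig(n_terms=20, dag_depth=2, n_proteins=400,
                          ppi_homophily=0.5, mean_degree=25.0,
                          function_balance=50.0, seed=6)
        dag = generate_dag(cfg)
        ann = generate_annotations(dag, cfg)
        table = generate_ppi(ann, cfg)
        within = sum(1 for a, b, _ in table if ann.latent[a] == ann.latent[b])
        cross = len(table) - within
        # equal weights: per-pair probability identical within and across
        proteins = sorted(ann.annotations)
        latent = np.array([ann.latent[p] for p in proteins])
        same = (latent[:, None] == latent[None, :])[np.triu_indices(len(latent), 1)]
        expected_ratio = same.sum() / (~same).sum()
        assert within / cross == pytest.approx(expected_ratio, rel=0.15)

    def test_mean_degree_within_15_percent(self):
        cfg = SynthConfig(n_terms=20, dag_depth=2, n_proteins=500,
                          ppi_homophily=0.7, mean_degree=12.0, seed=8)
        dag = generate_dag(cfg)
        ann = generate_annotations(dag, cfg)
        table = generate_ppi(ann, cfg)
        empirical = 2 * len(table) / cfg.n_proteins
        assert empirical == pytest.approx(12.0, rel=0.15)

    def test_shuffle_preserves_edge_count(self):
        dag = generate_dag(CFG)
        ann = generate_annotations(dag, CFG)
        table = generate_ppi(ann, CFG)
        shuf = shuffle_edges(table, substream(0, "x"))
        assert abs(len(shuf) - len(table)) <= 0.05 * len(table)  # rare merges


class TestScenario:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            scenario("D", seed=0)

    def test_bit_reproducible(self):
        a, b = scenario("A", seed=11), scenario("A", seed=11)
        assert a.train_ids == b.train_ids
        assert a.annotations.annotations == b.annotations.annotations
        p = a.train_ids[0]
        np.testing.assert_array_equal(a.store_a.get(p), b.store_a.get(p))
        assert sorted(a.ppi) == sorted(b.ppi)

    def test_split_is_partition(self):
        b = scenario("C", seed=3)
        all_ids = b.train_ids + b.val_ids + b.test_ids
        assert sorted(all_ids) == sorted(b.annotations.annotations)
        assert len(set(all_ids)) == len(all_ids)

    def test_signal_strength_orders_probe_quality(self):
        # increasing signal gives increasing label correlation in expectation
        from dataclasses import replace

        base = SynthConfig(n_terms=20, dag_depth=2, n_proteins=200, seed=14)
        maxima = []
        for s in (0.0, 1.0, 4.0):
            cfg = replace(base, signal_strength=s)
            dag = generate_dag(cfg)
            ann = generate_annotations(dag, cfg)
            store = generate_embeddings(ann, dag, "a", cfg)
            proteins = sorted(ann.annotations)
            X = store.batch(proteins)
            terms = sorted({t for ts in ann.annotations.values() for t in ts})
            y = np.array(
                [[t in ann.annotations[p] for t in terms] for p in proteins], float
            )
            keep = y.std(0) > 0
            r = np.corrcoef(X.T, y[:, keep].T)[: X.shape[1], X.shape[1]:]
            maxima.append(np.abs(r).max())
        assert maxima[0] < maxima[1] < maxima[2]


class TestRoundTrips:
    def test_bundle_passes_every_reader(self, tmp_path):
        b = scenario("A", seed=21)
        fasta = io.StringIO()
        from gopredict.data_io import write_fasta

        write_fasta(dummy_records(b.annotations, 21), fasta)
        fasta.seek(0)
        records = read_fasta(fasta)
        assert len(records) == len(b.annotations.annotations)

        obo = io.StringIO()
        write_obo(b.dag, obo)
        dag2 = parse_obo(obo.getvalue())
        assert dag2.terms == b.dag.terms
        assert dag2.parents == b.dag.parents

        tsv = io.StringIO()
        from gopredict.data_io import write_annotations

        write_annotations(b.annotations, tsv)
        tsv.seek(0)
        ann2 = read_annotations(tsv, dag2, "BP")
        assert ann2.annotations == b.annotations.annotations

        links = io.StringIO()
        for x, yq, c in sorted(b.ppi):
            links.write(f"{x} {yq} {c:.6f}\n")
        links.seek(0)
        table2 = read_string_links(links)
        assert len(table2) == len(b.ppi)
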