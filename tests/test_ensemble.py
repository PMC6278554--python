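import numpy as np
import pytest

from supermhc.clustering import SupertypeAssignment
from supermhc.ensemble import (
    RoutingError,
    default_routing,
    partition_training,
    predict,
    queries_from_dataset,
    train,
)
from supermhc.io import BindingDataset
from supermhc.rls import fit as rls_fit


@pytest.fixture(scope="module")
def assignment_with_diverse(small_world_assignment):
    """Truth-derived assignment with one DR molecule moved to diverse,
    so the diverse base learner exists and DR routing uses it."""
    labels = dict(small_world_assignment.labels)
    mover = sorted(m for m, l in labels.items() if l == "mainDR")[-1]
    labels[mover] = "diverse"
    return SupertypeAssignment(
        labels=labels,
        main_clusters=list(small_world_assignment.main_clusters),
        diverse=[mover],
    )


@pytest.fixture(scope="module")
def trained(small_world, assignment_with_diverse, engine):
    return train(small_world.dataset, assignment_with_diverse, engine=engine)


def unseen_query(world, isotype, peptide="ACDKLMNPQ"):
    """A query allele name absent from the assignment, borrowing the
    chains of an existing molecule of the same isotype."""
    donor = next(m for m, s in world.catalog.items()
                 if s.identity.isotype == isotype)
    seq = world.catalog[donor]
    name = {"DR": "DRB1_9901",
            "DP": "DPA19901-DPB19901",
            "DQ": "DQA19901-DQB19901"}[isotype]
    return (name, seq.alpha_region, seq.beta_region, peptide)


class TestPartitionTraining:
    def test_disjoint_exhaustive(self, small_world, assignment_with_diverse):
        parts = partition_training(small_world.dataset,
                                   assignment_with_diverse)
        assert sum(len(v) for v in parts.values()) == \
            len(small_world.dataset)
        seen = set()
        for recs in parts.values():
            ids = {id(r) for r in recs}
            assert not ids & seen
            seen |= ids

    def test_unassigned_molecule_falls_to_diverse(self, small_world):
        labels = {m: "mainDR" for m in small_world.catalog}
        missing = sorted(labels)[0]
        del labels[missing]
        assignment = SupertypeAssignment(labels=labels,
                                         main_clusters=["mainDR"])
        parts = partition_training(small_world.dataset, assignment)
        assert {r.allele_name for r in parts["diverse"]} == {missing}


class TestRouting:
    def test_default_routing_table(self):
        labels = ["mainDR", "mainDP", "mainDQ1", "mainDQ2", "diverse"]
        routing = default_routing(labels)
        assert routing == {
            "DR": ["mainDR", "diverse"],
            "DP": ["mainDP"],
            "DQ": ["mainDQ1", "mainDQ2"],
        }

    def test_empty_diverse_degrades_dr_routing(self):
        routing = default_routing(["mainDR", "mainDP", "mainDQ1",
                                   "mainDQ2"])
        assert routing["DR"] == ["mainDR"]

    def test_isotype_without_main_uses_diverse(self):
        routing = default_routing(["mainDR", "diverse"])
        assert routing["DP"] == ["diverse"]
        assert routing["DQ"] == ["diverse"]


class TestTrain:
    def test_one_model_per_nonempty_cluster(self, trained,
                                            assignment_with_diverse):
        expected = set(assignment_with_diverse.labels.values())
        assert set(trained.cluster_models) == expected

    def test_retraining_is_bit_identical(self, small_world,
                                         assignment_with_diverse, engine,
                                         tmp_path):
        m1 = train(small_world.dataset, assignment_with_diverse,
                   engine=engine)
        m2 = train(small_world.dataset, assignment_with_diverse,
                   engine=engine)
        p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
        m1.save(p1)
        m2.save(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_serialization_round_trip(self, trained, small_world, engine,
                                      tmp_path):
        path = tmp_path / "model.json"
        trained.save(path)
        loaded = type(trained).load(path)
        queries = queries_from_dataset(small_world.dataset)[:10]
        base, _ = predict(trained, queries, engine=engine)
        again, _ = predict(loaded, queries, engine=engine)
        assert np.array_equal(base, again)


class TestPredictRouting:
    def test_in_cluster_query_uses_exactly_one_model(self, trained,
                                                     small_world, engine):
        queries = queries_from_dataset(small_world.dataset)[:5]
        preds, provenance = predict(trained, queries, engine=engine)
        for q, prov in zip(queries, provenance):
            assert prov == [trained.assignment.labels[q[0]]]

    def test_in_cluster_matches_single_model(self, trained, small_world,
                                             engine):
        q = queries_from_dataset(small_world.dataset)[0]
        label = trained.assignment.labels[q[0]]
        preds, _ = predict(trained, [q], engine=engine)
        direct = trained.cluster_models[label].predict([q[1:]],
                                                       engine=engine)
        assert preds[0] == direct[0]

    @pytest.mark.parametrize(
        "isotype, expected_route",
        [
            ("DR", ["mainDR", "diverse"]),
            ("DP", ["mainDP"]),
            ("DQ", ["mainDQ1", "mainDQ2"]),
        ],
    )
    def test_unseen_allele_uniform_average(self, trained, small_world,
                                           engine, isotype, expected_route):
        q = unseen_query(small_world, isotype)
        preds, provenance = predict(trained, [q], engine=engine)
        assert provenance[0] == expected_route
        parts = [trained.cluster_models[lab].predict([q[1:]],
                                                     engine=engine)[0]
                 for lab in expected_route]
        assert abs(preds[0] - np.mean(parts)) < 1e-12

    def test_provenance_never_empty(self, trained, small_world, engine):
        queries = queries_from_dataset(small_world.dataset)[:8]
        queries.append(unseen_query(small_world, "DQ"))
        _, provenance = predict(trained, queries, engine=engine)
        assert all(len(p) >= 1 for p in provenance)

    def test_unroutable_isotype_error(self, small_world, engine):
        labels = {m: "mainDR" for m in small_world.catalog}
        assignment = SupertypeAssignment(labels=labels,
                                         main_clusters=["mainDR"])
        model = train(small_world.dataset, assignment, engine=engine,
                      routing={"DR": ["mainDR"]})
        with pytest.raises(RoutingError):
            predict(model, [unseen_query(small_world, "DP")], engine=engine)


class TestDegenerateSingleCluster:
    def test_collapses_to_plain_rls(self, small_world, engine):
        labels = {m: "mainDR" for m in small_world.catalog}
        assignment = SupertypeAssignment(labels=labels,
                                         main_clusters=["mainDR"])
        model = train(small_world.dataset, assignment, engine=engine)
        plain = rls_fit(small_world.dataset.triples(),
                        [r.affinity for r in small_world.dataset.records],
                        engine=engine)
        queries = queries_from_dataset(small_world.dataset)[:10]
        ens, _ = predict(model, queries, engine=engine)
        direct = plain.predict([q[1:] for q in queries], engine=engine)
        assert np.allclose(ens, direct, atol=1e-12)
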