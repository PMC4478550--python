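"""Ensemble graph: configuration, gating, consolidation, execution."""

import itertools

import numpy as np
import pytest

from ensloc import ensemble as E
from ensloc.features import FeatureVector


class StubModel:
    """Duck-typed BagEnsemble whose vote is a function of the feature row.

    The test feature convention: each cell's row encodes the intended
    outcome of named nodes as 0/1 flags, indexed by a shared node order.
    """

    def __init__(self, idx, registry_hash="stub"):
        self.idx = idx
        self.registry_hash = registry_hash

    def predict(self, X):
        return np.atleast_2d(X)[:, self.idx] > 0.5


@pytest.fixture(scope="module")
def config():
    return E.default_config()


@pytest.fixture(scope="module")
def node_order(config):
    return {n.classifier_id: i for i, n in enumerate(config.nodes)}


@pytest.fixture()
def stub_graph(config, node_order):
    models = {cid: StubModel(i) for cid, i in node_order.items()}
    return E.build_ensemble(config, models)


def make_row(node_order, positive_ids):
    row = np.zeros(len(node_order))
    for cid in positive_ids:
        row[node_order[cid]] = 1.0
    return row


class TestConfig:
    def test_default_graph_has_60_nodes_16_classes_20_subgroups(self, config):
        assert len(config.nodes) == 60
        assert len(config.classes) == 16
        assert len(config.subgroups) == 20

    def test_ids_span_levels_and_groups(self, config):
        assert {n.level for n in config.nodes} == {1, 2, 3}
        level3_groups = {n.group for n in config.nodes if n.level == 3}
        assert len(level3_groups) == 16
        # every level-3 node belongs to exactly one subgroup
        for n in config.level(3):
            if n.role != "refinement":
                assert (n.group, n.variant) in config.subgroups

    def test_training_object_counts_preserved(self, config):
        # spot-check transcription of the classifier table
        assert config.node("1.1.1").n_pos == 960 and config.node("1.1.1").n_neg == 1541
        assert config.node("3.3.2").name == "ER_CYTOPLASM"
        assert config.node("3.16.10").name == "SPINDLEPOLEONEDOT"
        assert sum(n.n_pos for n in config.nodes) > 60_000  # ~70K handpicked

    def test_missing_node_rejected_by_name(self, config, node_order):
        models = {cid: StubModel(i) for cid, i in node_order.items()}
        del models["3.5.1"]
        with pytest.raises(E.EnsembleBuildError, match="3.5.1"):
            E.build_ensemble(config, models)

    def test_mixed_registry_hashes_rejected(self, config, node_order):
        models = {cid: StubModel(i) for cid, i in node_order.items()}
        models["3.5.1"] = StubModel(node_order["3.5.1"], registry_hash="other")
        with pytest.raises(E.EnsembleBuildError, match="registr"):
            E.build_ensemble(config, models)


class TestClassifyCell:
    def test_dead_cell_short_circuits(self, stub_graph, node_order):
        row = make_row(node_order, ["1.1.1", "3.1.1", "2.1.3"])
        a = E.classify_cells(stub_graph, row[None, :])[0]
        assert a.qc == "dead"
        assert not a.memberships.any() and not a.classifiable
        assert a.trace == ["1.1.1"]  # nothing past the DEAD node

    def test_ghost_cell_flagged_after_dead(self, stub_graph, node_order):
        row = make_row(node_order, ["1.1.2"])
        a = E.classify_cells(stub_graph, row[None, :])[0]
        assert a.qc == "ghost"
        assert set(a.trace) == {"1.1.1", "1.1.2"}

    def test_er_membership_requires_all_four_nodes(self, stub_graph, node_order, config):
        er_nodes = ["3.3.1", "3.3.2", "3.3.3", "3.3.4"]
        row = make_row(node_order, ["2.1.1"] + er_nodes)
        a = E.classify_cells(stub_graph, row[None, :])[0]
        assert a.memberships[list(config.classes).index("ER")]
        # drop one discriminator -> conjunction fails
        row2 = make_row(node_order, ["2.1.1", "3.3.1", "3.3.3", "3.3.4"])
        a2 = E.classify_cells(stub_graph, row2[None, :])[0]
        assert not a2.memberships[list(config.classes).index("ER")]

    def test_unbudded_cell_never_reaches_budded_gated_nodes(self, stub_graph, node_order, config):
        budded_gated = [
            n.classifier_id for n in config.nodes if n.gate == "budded"
        ]
        row = make_row(node_order, ["2.1.1"] + budded_gated)
        a = E.classify_cells(stub_graph, row[None, :])[0]
        assert a.cycle_stage == "unbudded"
        assert not set(a.trace) & set(budded_gated)
        for cls in ("budneck", "bud", "budsite"):
            assert not a.memberships[list(config.classes).index(cls)]

    def test_budded_cell_skips_unbudded_variants(self, stub_graph, node_order, config):
        row = make_row(node_order, ["2.1.2", "3.15.1", "3.15.2"])
        a = E.classify_cells(stub_graph, row[None, :])[0]
        assert a.cycle_stage == "small-budded"
        assert "3.15.1" not in a.trace  # unbudded periphery variant gated out
        assert a.memberships[list(config.classes).index("cell periphery")]

    def test_stage_precedence_larger_morphology_wins(self, stub_graph, node_order):
        row = make_row(node_order, ["2.1.1", "2.1.2", "2.1.3"])
        a = E.classify_cells(stub_graph, row[None, :])[0]
        assert a.cycle_stage == "large/medium-budded"

    def test_undetermined_stage_routes_only_ungated_groups(self, stub_graph, node_order, config):
        # all cycle classifiers negative; fire everything at level 3
        lvl3 = [n.classifier_id for n in config.level(3)]
        a = E.classify_cells(stub_graph, make_row(node_order, lvl3)[None, :])[0]
        assert a.cycle_stage == E.UNDETERMINED
        got = set(a.assigned_classes())
        assert "cell periphery" not in got  # both variants are gated
        assert "cortical patches" not in got
        assert "spindle pole" in got  # one-dot variant is ungated
        assert "cytoplasm" in got and "nucleus" in got

    def test_refinement_annotates_without_vetoing(self, stub_graph, node_order, config):
        row = make_row(node_order, ["2.1.1", "3.1.1"])  # cytoplasm, refinement negative
        a = E.classify_cells(stub_graph, row[None, :])[0]
        assert a.memberships[list(config.classes).index("cytoplasm")]
        assert not a.sub_annotations.get("CYTOPLASMNOTNUCLEAR", False)
        row2 = make_row(node_order, ["2.1.1", "3.1.1", "3.1.2"])
        a2 = E.classify_cells(stub_graph, row2[None, :])[0]
        assert a2.sub_annotations.get("CYTOPLASMNOTNUCLEAR") is True

    def test_registry_mismatch_rejected(self, stub_graph):
        fv = FeatureVector(np.zeros(60), "nothestub")
        with pytest.raises(ValueError, match="registry"):
            E.classify_cell(stub_graph, fv)

    def test_deterministic(self, stub_graph, node_order):
        rng = np.random.default_rng(0)
        X = (rng.random((20, 60)) > 0.5).astype(float)
        a1 = E.classify_cells(stub_graph, X)
        a2 = E.classify_cells(stub_graph, X)
        for x, y in zip(a1, a2):
            assert np.array_equal(x.memberships, y.memberships)
            assert x.qc == y.qc and x.cycle_stage == y.cycle_stage


class TestConsolidateGroup:
    def test_singleton_group_passes_through(self, config):
        assert E.consolidate_group(config, "3.5 Mitochondria", {"3.5.1": True}) is True
        assert E.consolidate_group(config, "3.5 Mitochondria", {"3.5.1": False}) is False

    def test_discriminator_veto(self, config):
        decisions = {"3.9.1": True, "3.9.2": True, "3.9.3": True, "3.9.4": False}
        assert E.consolidate_group(config, "3.9 Peroxisome", decisions) is False
        decisions["3.9.4"] = True
        assert E.consolidate_group(config, "3.9 Peroxisome", decisions) is True

    def test_spindle_pole_disjunction_matches_enumeration_oracle(self, config):
        # enumerate every decision pattern of the three variants
        far = ["3.16.1", "3.16.2", "3.16.3", "3.16.4"]
        close = ["3.16.5", "3.16.6", "3.16.7", "3.16.8", "3.16.9"]
        one = ["3.16.10"]
        ids = far + close + one
        for bits in itertools.product([False, True], repeat=len(ids)):
            decisions = dict(zip(ids, bits))
            oracle = (
                all(decisions[i] for i in far)
                or all(decisions[i] for i in close)
                or decisions["3.16.10"]
            )
            assert E.consolidate_group(config, "3.16 Spindle Pole", decisions) == oracle

    def test_one_dot_only_still_positive(self, config):
        decisions = {i: False for i in (
            "3.16.1", "3.16.2", "3.16.3", "3.16.4",
            "3.16.5", "3.16.6", "3.16.7", "3.16.8", "3.16.9",
        )}
        decisions["3.16.10"] = True
        assert E.consolidate_group(config, "3.16 Spindle Pole", decisions) is True

    def test_gated_out_variant_ignored(self, config):
        # unbudded cell: only the unbudded cortical-patches variant executed
        decisions = {"3.11.1": True, "3.11.2": True, "3.11.3": True}
        assert E.consolidate_group(config, "3.11 Cortical Patches", decisions) is True

    def test_partial_variant_decisions_rejected(self, config):
        with pytest.raises(ValueError, match="missing"):
            E.consolidate_group(config, "3.3 ER", {"3.3.1": True, "3.3.2": True})

    def test_unknown_group_rejected(self, config):
        with pytest.raises(KeyError):
            E.consolidate_group(config, "3.99 Lysosome", {})


class TestAssignmentVector:
    def test_qc_failure_forbids_memberships(self):
        with pytest.raises(ValueError, match="membership"):
            E.AssignmentVector(
                cell_ref=(1,),
                qc="dead",
                cycle_stage=E.UNDETERMINED,
                memberships=np.ones(16, dtype=bool),
            )

    def test_multi_membership_and_empty_allowed(self):
        m = np.zeros(16, dtype=bool)
        m[[2, 5]] = True
        a = E.AssignmentVector((1,), "pass", "unbudded", m)
        assert a.classifiable and len(a.assigned_classes()) == 2
        b = E.AssignmentVector((2,), "pass", "unbudded", np.zeros(16, dtype=bool))
        assert not b.classifiable
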