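"""File-dialect readers, the toxicity/synergy join, and the tidy round-trip."""

import numpy as np
import pytest

from combotox import data_io
from combotox.data_io import FormatError
from combotox.datatypes import ComboObservation, Severity, ToxicityLabel


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestSynergyTable:
    def test_single_score_column(self, tmp_path):
        p = write(tmp_path, "s.csv", "drug_a,drug_b,cell_line,bliss\nA,B,c1,1.5\nA,C,c1,2\nB,C,c2,-1\n")
        obs = data_io.load_synergy_table(p)
        assert len(obs) == 3
        assert all(set(o.synergy) == {"bliss"} for o in obs)

    def test_swapped_drugs_share_canonical_key(self, tmp_path):
        p = write(tmp_path, "s.csv", "drug_a,drug_b,cell_line,bliss\nB,A,c1,1\nA,B,c2,2\n")
        obs = data_io.load_synergy_table(p)
        assert obs[0].pair == obs[1].pair == ("a", "b")

    def test_blank_cell_recorded_absent(self, tmp_path):
        p = write(tmp_path, "s.csv", "drug_a,drug_b,cell_line,bliss,zip\nA,B,c1,1.0,\n")
        obs = data_io.load_synergy_table(p)
        assert "zip" not in obs[0].synergy and obs[0].synergy["bliss"] == 1.0

    def test_unparseable_cell_warns_and_drops(self, tmp_path, caplog):
        p = write(tmp_path, "s.csv", "drug_a,drug_b,cell_line,bliss\nA,B,c1,oops\n")
        obs = data_io.load_synergy_table(p)
        assert "bliss" not in obs[0].synergy
        assert any("unparseable" in r.message for r in caplog.records)

    def test_missing_column_names_the_column(self, tmp_path):
        p = write(tmp_path, "s.csv", "drug_a,drug_b,bliss\nA,B,1\n")
        with pytest.raises(FormatError, match="cell_line"):
            data_io.load_synergy_table(p)

    def test_drugcomb_dialect_columns(self, tmp_path):
        p = write(
            tmp_path, "dc.csv",
            "drug_row,drug_col,cell_line_name,synergy_bliss,S_max\nTamoxifen,ASPIRIN,MCF7,3.2,0.4\n",
        )
        obs = data_io.load_synergy_table(p, dialect="drugcomb")
        assert obs[0].pair == ("aspirin", "tamoxifen")
        assert obs[0].synergy == {"bliss": 3.2, "s_max": 0.4}


class TestToxicityTable:
    def test_drugbank_numeric_levels(self, tmp_path):
        p = write(tmp_path, "t.csv", "drug1,drug2,level\nA,B,2\nA,C,0\n")
        m = data_io.load_toxicity_table(p, dialect="drugbank")
        assert m[("a", "b")].level == Severity.MAJOR
        assert m[("a", "c")].level == Severity.MINOR

    def test_ddinter_words_and_unknown_dropped(self, tmp_path):
        p = write(tmp_path, "t.csv", "drug1,drug2,severity\nA,B,Moderate\nA,C,Unknown\n")
        m = data_io.load_toxicity_table(p, dialect="ddinter")
        assert m[("a", "b")].level == Severity.MODERATE
        assert ("a", "c") not in m

    def test_conflicting_duplicates_keep_max_severity(self, tmp_path):
        p = write(tmp_path, "t.csv", "drug1,drug2,severity\nA,B,Minor\nB,A,Major\n")
        m = data_io.load_toxicity_table(p, dialect="ddinter")
        assert m[("a", "b")].level == Severity.MAJOR

    def test_first_wins_policy(self, tmp_path):
        p = write(tmp_path, "t.csv", "drug1,drug2,severity\nA,B,Minor\nA,B,Major\n")
        m = data_io.load_toxicity_table(p, dialect="ddinter", duplicate_policy="first")
        assert m[("a", "b")].level == Severity.MINOR

    def test_empty_after_filtering_is_hard_error(self, tmp_path):
        p = write(tmp_path, "t.csv", "drug1,drug2,severity\nA,B,Unknown\n")
        with pytest.raises(FormatError):
            data_io.load_toxicity_table(p, dialect="ddinter")


class TestTargets:
    def test_aggregation_and_duplicates(self, tmp_path):
        p = write(tmp_path, "tg.csv", "drug,protein\nd1,P1\nd1,P2\nd2,P1\nd1,P1\n")
        m = data_io.load_targets(p)
        assert m == {"d1": {"P1", "P2"}, "d2": {"P1"}}

    def test_isoform_suffix_stripping(self, tmp_path):
        p = write(tmp_path, "tg.csv", "drug,protein\nd1,P12345-2\n")
        assert data_io.load_targets(p)["d1"] == {"P12345"}
        assert data_io.load_targets(p, strip_isoforms=False)["d1"] == {"P12345-2"}

    def test_empty_file(self, tmp_path):
        p = write(tmp_path, "tg.csv", "drug,protein\n")
        assert data_io.load_targets(p) == {}


class TestPathways:
    def _files(self, tmp_path):
        low = write(tmp_path, "low.tsv", "X\tp3\tp3 pathway\tHomo sapiens\nY\tq9\tq\tMus musculus\n")
        al = write(
            tmp_path, "all.tsv",
            "X\tp1\tn\tHomo sapiens\nX\tp2\tn\tHomo sapiens\nX\tp3\tn\tHomo sapiens\n",
        )
        return low, al

    def test_two_views_and_species_filter(self, tmp_path):
        low, al = self._files(tmp_path)
        h = data_io.load_pathways(low, al)
        assert h.lowest["X"] == {"p3"}
        assert h.all["X"] == {"p1", "p2", "p3"}
        assert "Y" not in h.lowest  # non-matching species excluded

    def test_inconsistent_protein_unioned(self, tmp_path):
        low = write(tmp_path, "low2.tsv", "Z\tp9\tn\tHomo sapiens\n")
        al = write(tmp_path, "all2.tsv", "Z\tp1\tn\tHomo sapiens\n")
        h = data_io.load_pathways(low, al)
        assert h.all["Z"] == {"p1", "p9"}  # superset repaired by union

    def test_absent_protein_views_empty(self, tmp_path):
        low, al = self._files(tmp_path)
        h = data_io.load_pathways(low, al)
        assert h.lowest.get("NOPE", frozenset()) == frozenset()


class TestNetwork:
    def test_triangle_and_score_threshold(self, tmp_path):
        edges = write(tmp_path, "e.txt", "protein1 protein2 combined_score\nn1 n2 900\nn2 n3 900\nn1 n3 150\n")
        idmap = write(tmp_path, "m.tsv", "uniprot\tnode\nP1\tn1\nP2\tn2\n")
        net = data_io.load_network(edges, idmap, min_edge_score=0)
        assert net.graph.number_of_nodes() == 3 and net.graph.number_of_edges() == 3
        net2 = data_io.load_network(edges, idmap, min_edge_score=500)
        assert net2.graph.number_of_edges() == 2

    def test_counts_match_manual_dedup_oracle(self, tmp_path):
        r = np.random.default_rng(5)
        lines = ["protein1 protein2 combined_score"]
        edges = set()
        for _ in range(60):
            u, v = r.integers(0, 20, 2)
            if u == v:
                continue
            lines.append(f"n{u} n{v} 500")
            edges.add(frozenset((f"n{u}", f"n{v}")))
        path = write(tmp_path, "rand.txt", "\n".join(lines) + "\n")
        idmap = write(tmp_path, "m.tsv", "uniprot\tnode\n")
        net = data_io.load_network(path, idmap)
        assert net.graph.number_of_edges() == len(edges)
        assert set(net.graph.nodes) == {n for e in edges for n in e}

    def test_idmap_collision_first_wins(self, tmp_path):
        edges = write(tmp_path, "e.txt", "protein1 protein2 combined_score\nn1 n2 900\n")
        idmap = write(tmp_path, "m.tsv", "uniprot\tnode\nP1\tn1\nP1\tn2\n")
        net = data_io.load_network(edges, idmap)
        assert net.id_map["P1"] == "n1"


def _obs(a, b, cl="c1", **synergy):
    return ComboObservation(drug_a=a, drug_b=b, cell_line=cl, synergy=synergy or {"bliss": 1.0})


class TestAssemble:
    def test_filter_drops_unlabelled_pairs_and_logs(self):
        obs = [_obs("a", "b"), _obs("a", "c"), _obs("b", "c"), _obs("a", "d"), _obs("c", "d")]
        tox = {
            "drugbank": {
                p: ToxicityLabel(Severity.MAJOR, "drugbank")
                for p in [("a", "b"), ("a", "c"), ("b", "c")]
            }
        }
        ds = data_io.assemble_dataset(obs, tox)
        assert len(ds.observations) == 3
        log = ds.provenance["filter_log"]
        assert log["observations_in"] == 5 and log["observations_kept"] == 3

    def test_total_map_is_identity_filter(self):
        obs = [_obs("a", "b"), _obs("a", "c")]
        tox = {"drugbank": {o.pair: ToxicityLabel(Severity.MINOR, "drugbank") for o in obs}}
        assert len(data_io.assemble_dataset(obs, tox).observations) == 2

    def test_either_source_retains_observation(self):
        obs = [_obs("a", "b"), _obs("a", "c"), _obs("b", "c")]
        tox = {
            "drugbank": {("a", "b"): ToxicityLabel(Severity.MINOR, "drugbank")},
            "ddinter": {("a", "c"): ToxicityLabel(Severity.MAJOR, "ddinter")},
        }
        ds = data_io.assemble_dataset(obs, tox)
        assert {o.pair for o in ds.observations} == {("a", "b"), ("a", "c")}
        assert set(ds.observations[0].toxicity) == {"drugbank"}

    def test_join_symmetric_in_pair_order(self):
        tox = {"drugbank": {("a", "b"): ToxicityLabel(Severity.MINOR, "drugbank")}}
        d1 = data_io.assemble_dataset([_obs("a", "b")], tox)
        d2 = data_io.assemble_dataset([_obs("b", "a")], tox)
        assert d1.observations[0].pair == d2.observations[0].pair

    def test_zero_survivors_is_hard_error(self):
        with pytest.raises(ValueError):
            data_io.assemble_dataset([_obs("a", "b")], {"drugbank": {}})


class TestRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path):
        obs = [
            ComboObservation(
                drug_a="b", drug_b="a", cell_line="c1",
                synergy={"bliss": 1.25, "zip": -0.5},
            ),
            _obs("a", "c"),
        ]
        tox = {
            "drugbank": {
                ("a", "b"): ToxicityLabel(Severity.MAJOR, "drugbank"),
                ("a", "c"): ToxicityLabel(Severity.MINOR, "drugbank"),
            }
        }
        ds = data_io.assemble_dataset(obs, tox, targets={"a": frozenset({"P1"})}, smiles={"a": "CCO"})
        data_io.write_dataset(ds, tmp_path / "out")
        back = data_io.read_dataset(tmp_path / "out")
        assert [o.pair for o in back.observations] == [o.pair for o in ds.observations]
        assert [o.synergy for o in back.observations] == [o.synergy for o in ds.observations]
        assert [o.toxicity for o in back.observations] == [o.toxicity for o in ds.observations]
        assert back.drugs == ds.drugs
        assert back.provenance == ds.provenance
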