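import numpy as np
import pandas as pd
import pytest

from gmebiome import taxonomy as tx
from gmebiome import umi_amplicon as ua


def _lineage_table(rows):
    return pd.DataFrame(rows)


class TestSearchReference:
    def test_exact_match_is_100(self):
        ref = {"R0001": "ACGTACGTAC" * 10}
        hits = tx.search_reference({"q": ref["R0001"]}, ref)
        assert hits[0].identity == 100.0

    def test_single_mismatch_in_100_gives_99(self):
        seq = "ACGT" * 25
        query = "T" + seq[1:]
        hits = tx.search_reference({"q": query}, {"R0001": seq})
        assert hits[0].identity == pytest.approx(99.0)

    def test_all_n_query_below_floor(self):
        hits = tx.search_reference({"q": "N" * 100}, {"R0001": "ACGT" * 25})
        assert hits == []

    def test_query_substring_of_subject_matches_fully(self):
        seq = "ACGTAACCGGTTACGT" * 20
        hits = tx.search_reference({"q": seq[40:140]}, {"R0001": seq})
        assert hits[0].identity == 100.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            tx.search_reference({"q": "ACGT"}, {})


class TestAssignTopHit:
    lineage = _lineage_table([
        {"reference_id": "R0007", "domain": "Bacteria", "phylum": "P",
         "class": "C", "order": "O", "family": "F", "genus": "GenusA"},
        {"reference_id": "R0012", "domain": "Bacteria", "phylum": "P",
         "class": "C", "order": "O", "family": "F", "genus": "GenusB"},
        {"reference_id": "R0003", "domain": "Bacteria", "phylum": "P",
         "class": "C", "order": "O", "family": "F", "genus": ""},
    ])

    def test_single_best_hit_wins(self):
        hits = [tx.ReferenceHit("q", "R0012", 99.0, "ribosomal-reference"),
                tx.ReferenceHit("q", "R0007", 95.0, "ribosomal-reference")]
        assert tx.assign_top_hit(hits, self.lineage)["q"].subject == "R0012"

    def test_named_genus_preferred_on_tie(self):
        hits = [tx.ReferenceHit("q", "R0003", 99.0, "ribosomal-reference"),
                tx.ReferenceHit("q", "R0012", 99.0, "ribosomal-reference")]
        assert tx.assign_top_hit(hits, self.lineage)["q"].subject == "R0012"

    def test_earliest_id_on_named_tie(self):
        hits = [tx.ReferenceHit("q", "R0012", 99.0, "ribosomal-reference"),
                tx.ReferenceHit("q", "R0007", 99.0, "ribosomal-reference")]
        assert tx.assign_top_hit(hits, self.lineage)["q"].subject == "R0007"

    def test_natural_ordering_not_lexicographic(self):
        lineage = _lineage_table([
            {"reference_id": f"R{i}", "genus": f"g{i}"} for i in (2, 10)])
        hits = [tx.ReferenceHit("q", "R10", 99.0, "ribosomal-reference"),
                tx.ReferenceHit("q", "R2", 99.0, "ribosomal-reference")]
        assert tx.assign_top_hit(hits, lineage)["q"].subject == "R2"

    def test_order_invariance(self):
        hits = [tx.ReferenceHit("q", "R0012", 99.0, "ribosomal-reference"),
                tx.ReferenceHit("q", "R0007", 99.0, "ribosomal-reference"),
                tx.ReferenceHit("q", "R0003", 97.0, "ribosomal-reference")]
        a = tx.assign_top_hit(hits, self.lineage)["q"]
        b = tx.assign_top_hit(hits[::-1], self.lineage)["q"]
        assert a == b


class TestExcludeHost:
    def _assign(self, ident):
        return {"q": tx.ReferenceHit("q", "R0001", ident,
                                     "ribosomal-reference")}

    def test_better_host_hit_excluded(self):
        hits = [tx.ReferenceHit("q", "H1", 100.0, "host-genome")]
        kept, excluded = tx.exclude_host(self._assign(85.0), hits)
        assert excluded == ["q"] and not kept

    def test_better_ribosomal_hit_kept(self):
        hits = [tx.ReferenceHit("q", "H1", 80.0, "host-genome")]
        kept, excluded = tx.exclude_host(self._assign(99.0), hits)
        assert "q" in kept and not excluded

    def test_tie_keeps_query(self):
        hits = [tx.ReferenceHit("q", "H1", 99.0, "host-genome")]
        kept, excluded = tx.exclude_host(self._assign(99.0), hits)
        assert "q" in kept

    def test_host_only_query_excluded(self):
        hits = [tx.ReferenceHit("q2", "H1", 95.0, "host-genome")]
        kept, excluded = tx.exclude_host({}, hits)
        assert excluded == ["q2"]

    def test_no_host_hits_keeps_all(self):
        kept, excluded = tx.exclude_host(self._assign(90.0), [])
        assert "q" in kept and not excluded


class TestValidateNames:
    accepted = pd.DataFrame([
        {"rank": "domain", "name": "Bacteria"},
        {"rank": "phylum", "name": "P"}, {"rank": "class", "name": "C"},
        {"rank": "order", "name": "O"}, {"rank": "family", "name": "F"},
        {"rank": "genus", "name": "GenusA"},
    ])

    def test_fully_accepted_unchanged(self):
        lin = {"domain": "Bacteria", "phylum": "P", "class": "C",
               "order": "O", "family": "F", "genus": "GenusA"}
        assert tx.validate_names(lin, self.accepted) == lin

    def test_withheld_family_becomes_notassigned(self):
        lin = {"domain": "Bacteria", "phylum": "P", "class": "C",
               "order": "O", "family": "Fx", "genus": "GenusA"}
        out = tx.validate_names(lin, self.accepted)
        assert out["family"] == tx.NOT_ASSIGNED
        assert out["genus"] == "GenusA" and out["phylum"] == "P"

    def test_rank_aware_lookup(self):
        # a genus name listed only under family rank is not accepted as genus
        lin = {"domain": "Bacteria", "phylum": "P", "class": "C",
               "order": "O", "family": "F", "genus": "F"}
        assert tx.validate_names(lin, self.accepted)["genus"] == tx.NOT_ASSIGNED

    def test_empty_lineage_all_notassigned(self):
        out = tx.validate_names({}, self.accepted)
        assert all(v == tx.NOT_ASSIGNED for v in out.values())


class TestAggregate:
    def _table(self):
        counts = pd.DataFrame({"ASV_1": [3, 2], "ASV_2": [1, 0],
                               "ASV_3": [2, 5]},
                              index=["s1", "s2"])
        seqs = {a: f"SEQ{i}" for i, a in enumerate(counts.columns)}
        return ua.AsvTable(counts=counts, sequences=seqs)

    def _assignments(self):
        return {"ASV_1": tx.ReferenceHit("ASV_1", "R0001", 100, "ribosomal-reference"),
                "ASV_2": tx.ReferenceHit("ASV_2", "R0001", 99, "ribosomal-reference"),
                "ASV_3": tx.ReferenceHit("ASV_3", "R0002", 100, "ribosomal-reference")}

    def _lineages(self):
        base = {"domain": "Bacteria", "phylum": "P", "class": "C",
                "order": "O"}
        return {"ASV_1": base | {"family": "F1", "genus": "G1"},
                "ASV_2": base | {"family": "F1", "genus": "G1"},
                "ASV_3": base | {"family": "F2", "genus": "G2"}}

    def test_same_top_hit_columns_summed(self):
        otu = tx.aggregate(self._table(), self._assignments(),
                           self._lineages(), rank="otu")
        assert list(otu.counts["R0001"]) == [4, 2]
        assert list(otu.counts["R0002"]) == [2, 5]

    def test_distinct_families_change_only_labels(self):
        fam = tx.aggregate(self._table(), self._assignments(),
                           self._lineages(), rank="family")
        assert set(fam.counts.columns) == {"F1", "F2"}
        assert list(fam.counts["F2"]) == [2, 5]

    def test_totals_conserved_at_every_rank(self):
        table = self._table()
        total = table.counts.to_numpy().sum()
        for rank in ("otu", "genus", "family", "order"):
            agg = tx.aggregate(table, self._assignments(), self._lineages(),
                               rank=rank)
            assert agg.grand_total == total

    def test_notassigned_bins_distinct_per_parent(self):
        lineages = self._lineages()
        lineages["ASV_1"]["genus"] = tx.NOT_ASSIGNED
        lineages["ASV_3"] = {"domain": "Bacteria", "phylum": "P2",
                             "class": "C", "order": "O",
                             "family": "F2", "genus": tx.NOT_ASSIGNED}
        gen = tx.aggregate(self._table(), self._assignments(), lineages,
                           rank="genus")
        unassigned = [c for c in gen.counts.columns if c.startswith(tx.NOT_ASSIGNED)]
        assert len(unassigned) == 2   # different parents, different bins


class TestEndToEnd:
    def test_error_free_asvs_assigned_to_generating_taxon(self, clean_read_run):
        table = ua.count_umis(clean_read_run["records"])
        ref = clean_read_run["reference"]
        filtered, kept, lineages, excluded = tx.assign_pipeline(
            table, ref["reference"], ref["lineage"], ref["accepted_names"],
            host=ref["host"])
        seq_to_taxon = {v: k for k, v in ref["reference"].items()}
        assert len(kept) == len(table.counts.columns)
        for asv, hit in kept.items():
            assert hit.subject == seq_to_taxon[table.sequences[asv]]
            assert hit.identity == 100.0
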