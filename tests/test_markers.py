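"""Marker detection, the reverse-methanogenesis audit, and the rule engine."""

import pandas as pd
import pytest

from magpot.markers import (
    UNIDENTIFIED,
    assign_metabolism,
    check_reverse_methanogenesis,
    detect_markers,
)


def ann(mag, ids):
    return pd.DataFrame(
        [(mag, f"{mag}_g{i}", a) for i, a in enumerate(ids)],
        columns=["mag_id", "gene_id", "annotation_id"])


def row(presence_matrix, mag):
    return presence_matrix.loc[mag].to_dict()


class TestDetectMarkers:
    def test_planted_markers_and_only_those_detected(self, catalog):
        table = ann("KA1", ["dsrA", "napA", "cooS"])
        m = detect_markers(table, catalog)
        expected_true = {"dsrAB", "napA", "cooS"}
        for symbol in catalog.symbols:
            assert m.at["KA1", symbol] == (symbol in expected_true)

    def test_missing_mag_gets_all_false_row(self, catalog):
        m = detect_markers(ann("KA1", ["sqr"]), catalog, mag_ids=["KA1", "KA2"])
        assert not m.loc["KA2"].any()

    def test_any_alias_suffices(self, catalog):
        for alias in ("dsrA", "dsrB", "K11180"):
            m = detect_markers(ann("KA1", [alias]), catalog)
            assert m.at["KA1", "dsrAB"]

    def test_require_all_complex_needs_complete_complement(self, catalog):
        partial = detect_markers(ann("KA1", ["bzdN", "bzdO"]), catalog)
        assert not partial.at["KA1", "bzd"]
        complete = detect_markers(ann("KA1", ["bzdN", "bzdO", "bzdP", "bzdQ"]), catalog)
        assert complete.at["KA1", "bzd"]

    def test_row_order_invariance(self, catalog):
        ids = ["sqr", "napA", "coxA", "hydA"]
        fwd = detect_markers(ann("KA1", ids), catalog)
        rev = detect_markers(ann("KA1", ids[::-1]), catalog)
        pd.testing.assert_frame_equal(fwd, rev)


CORE = ["fmdA", "ftr", "mch", "mtd", "mer", "mtrA", "mcrA"]
ELECTRON = ["fpoA", "hdrA", "hdrD", "rnfA"]


class TestReverseMethanogenesis:
    def test_full_core_without_hydrogenases_is_candidate(self, catalog):
        chk = check_reverse_methanogenesis(CORE + ELECTRON, catalog, "KA19")
        assert chk.is_candidate
        assert all(chk.core_steps_present.values())
        assert all(chk.electron_transfer_present.values())
        assert chk.missing_steps == ()

    def test_any_canonical_hydrogenase_breaks_the_verdict(self, catalog):
        for hyd in ("frhA", "mvhA", "echA", "vhoA"):
            chk = check_reverse_methanogenesis(CORE + [hyd], catalog)
            assert not chk.is_candidate

    def test_methylotrophy_methyltransferase_breaks_the_verdict(self, catalog):
        chk = check_reverse_methanogenesis(CORE + ["mtaB"], catalog)
        assert not chk.is_candidate

    def test_missing_step_is_named(self, catalog):
        chk = check_reverse_methanogenesis(
            [g for g in CORE if g != "mer"], catalog)
        assert not chk.is_candidate
        assert chk.missing_steps == ("mer",)

    def test_nitrate_and_sulfate_absence_flags_reported(self, catalog):
        chk = check_reverse_methanogenesis(CORE + ["narG", "dsrA"], catalog)
        assert not chk.nitrate_genes_absent["nar"]
        assert not chk.sulfate_genes_absent["dsrAB"]
        # these flags are informational: the verdict still stands
        assert chk.is_candidate


class TestRuleEngine:
    def _presence(self, catalog, symbols):
        return {s: (s in symbols) for s in catalog.symbols}

    def test_reverse_methanogenesis_label(self, catalog):
        chk = check_reverse_methanogenesis(CORE, catalog, "KA19")
        call = assign_metabolism(
            self._presence(catalog, {"mcrA", "cooS"}), set(), chk, "KA19")
        assert call.labels == ("anaerobic methane oxidation",)

    def test_wl_autotroph_with_nitrate_and_sulfite(self, catalog):
        call = assign_metabolism(
            self._presence(catalog, {"cooS", "hybC", "napA", "dsrAB"}),
            {"WL"}, None, "KA5")
        assert call.labels == (
            "autotrophic", "nitrate reduction", "sulfite/sulfate reduction",
            "H2 utilization")
        assert call.evidence["nitrate reduction"] == ("napA",)

    def test_all_false_row_is_unidentified(self, catalog):
        call = assign_metabolism(self._presence(catalog, set()), set(), None)
        assert call.labels == (UNIDENTIFIED,)

    def test_nosZ_alone_fires_nothing(self, catalog):
        call = assign_metabolism(self._presence(catalog, {"nosZ"}), set(), None)
        assert call.labels == (UNIDENTIFIED,)

    def test_denitrification_needs_narG_and_nosZ(self, catalog):
        call = assign_metabolism(
            self._presence(catalog, {"narG", "nosZ", "coxA"}), set(), None)
        assert "denitrification" in call.labels
        assert "nitrate reduction" not in call.labels

    def test_acetogenic_needs_cooS_and_cooF_with_wl(self, catalog):
        without_cooF = assign_metabolism(
            self._presence(catalog, {"cooS"}), {"WL"}, None)
        assert "acetogenic" not in without_cooF.labels
        with_cooF = assign_metabolism(
            self._presence(catalog, {"cooS", "cooF"}), {"WL"}, None)
        assert "acetogenic" in with_cooF.labels

    def test_fermenter_hydrogenase_not_double_labelled(self, catalog):
        call = assign_metabolism(
            self._presence(catalog, {"Fe-hyd", "hybC"}), set(), None)
        assert call.labels == ("fermentation",)

    def test_ccoN_alone_gives_no_lifestyle_label(self, catalog):
        call = assign_metabolism(
            self._presence(catalog, {"ccoN", "hybC"}), set(), None)
        assert call.labels == ("H2 utilization",)

    def test_coxA_facultative_split(self, catalog):
        aerobe = assign_metabolism(
            self._presence(catalog, {"coxA", "hybC"}), set(), None)
        assert "aerobic" in aerobe.labels
        facultative = assign_metabolism(
            self._presence(catalog, {"coxA", "Fe-hyd"}), set(), None)
        assert facultative.labels == ("facultatively anaerobic",)

    def test_adding_marker_never_removes_labels(self, catalog):
        base_syms = {"sqr", "napA"}
        base = assign_metabolism(self._presence(catalog, base_syms), set(), None)
        for extra in ("GH1", "pMMO", "dsrAB", "hyaB"):
            grown = assign_metabolism(
                self._presence(catalog, base_syms | {extra}), set(), None)
            assert set(base.labels) <= set(grown.labels)


class TestCommunityReproduction:
    def test_reference_label_column_reproduced(
            self, marker_table, community_annotations, catalog, definitions):
        """The 33-bin community's putative-metabolism column is recovered
        from the planted gene complements under the documented rule order."""
        from magpot.pathways import call_autotrophs, completeness_matrix

        mags = list(marker_table["bin_id"])
        presence = detect_markers(community_annotations, catalog, mag_ids=mags)
        matrix = completeness_matrix(community_annotations, definitions, mag_ids=mags)
        calls = call_autotrophs(matrix, community_annotations, definitions)
        by_mag = {m: set(g["annotation_id"])
                  for m, g in community_annotations.groupby("mag_id")}
        for r in marker_table.itertuples(index=False):
            chk = check_reverse_methanogenesis(
                by_mag.get(r.bin_id, ()), catalog, r.bin_id)
            auto = {p for m, p in calls if m == r.bin_id}
            call = assign_metabolism(
                presence.loc[r.bin_id].to_dict(), auto, chk, r.bin_id)
            assert call.labels == tuple(r.expected_labels), r.bin_id

    def test_exactly_six_autotroph_calls(
            self, marker_table, community_annotations, definitions):
        from magpot.pathways import call_autotrophs, completeness_matrix

        mags = list(marker_table["bin_id"])
        matrix = completeness_matrix(community_annotations, definitions, mag_ids=mags)
        calls = call_autotrophs(matrix, community_annotations, definitions)
        assert len(calls) == 6
        assert {m for m, _ in calls} == {"KA5", "KA7", "KA14", "KA16", "KA22", "KA26"}
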