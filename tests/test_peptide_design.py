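import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surfmut.annotation_store import AnnotationStore, ProteinRecord, TopologyFeature
from surfmut.msp_classifier import classify_cohort
from surfmut.peptide_design import (
    DesignError,
    design_window,
    export_panel_fasta,
    load_reference_pairs,
    panel_manifest_frame,
    pool_cocktail,
    select_panel,
    validate_pair,
)
from surfmut.variant_io import MissenseVariant, ProteinChange

from conftest import AA20, repeat_seq

# hand-verified from the golden fixture: wild-type residue, window offset, mutant
EXPECTED_SUBSTITUTIONS = [
    ("N", 6, "T"),
    ("H", 11, "L"),
    ("S", 4, "P"),
    ("S", 11, "N"),
    ("G", 4, "E"),
    ("Q", 11, "E"),
    ("D", 11, "N"),
    ("I", 9, "T"),
    ("D", 4, "H"),
    ("P", 9, "S"),
]


class TestReferencePairs:
    def test_all_ten_pass(self):
        pairs = load_reference_pairs()
        assert len(pairs) == 10
        for pair in pairs:
            report = validate_pair(pair["wildtype"], pair["mutant"])
            assert report.passed, pair["id"]

    def test_substitution_triples(self):
        got = []
        for pair in load_reference_pairs():
            r = validate_pair(pair["wildtype"], pair["mutant"])
            got.append((r.ref_aa, r.offset, r.alt_aa))
        assert got == EXPECTED_SUBSTITUTIONS

    def test_all_windows_are_14mers(self):
        for pair in load_reference_pairs():
            assert len(pair["mutant"]) == len(pair["wildtype"]) == 14


class TestValidatePair:
    def test_known_single_substitution(self):
        report = validate_pair("RVRNTHSENAHTGV", "RVRNTHSENALTGV")
        assert report.passed
        assert (report.ref_aa, report.offset, report.alt_aa) == ("H", 11, "L")

    def test_identical_sequences_fail(self):
        report = validate_pair("PEPTIDE".replace("P", "A"), "PEPTIDE".replace("P", "A"))
        assert not report.passed and "identical_sequences" in report.reasons

    def test_length_mismatch_fails(self):
        report = validate_pair("ACDEF", "ACDE")
        assert not report.passed and "length_mismatch" in report.reasons

    def test_two_substitutions_fail(self):
        report = validate_pair("ACDEF", "GCDEG")
        assert not report.passed and "hamming_distance_2" in report.reasons

    def test_noncanonical_alphabet_fails(self):
        report = validate_pair("ACXEF", "ACDEF")
        assert not report.passed and "noncanonical_alphabet" in report.reasons


def embed_record(window, at, total=60, accession="EMB1", gene="Emb1", **kw):
    """Protein whose sequence contains `window` starting at 1-based `at`."""
    seq = repeat_seq(total)
    seq = seq[: at - 1] + window + seq[at - 1 + len(window) :]
    return ProteinRecord(accession, gene, seq, **kw)


class TestDesignWindow:
    def test_reproduces_golden_pair(self):
        rec = embed_record("FSIVRNSLSHPPPD", at=21)
        change = ProteinChange("N", 26, "T")  # the N inside the embedded window
        window = design_window(rec, change, length=14, window_start=21)
        assert window.wildtype_seq == "FSIVRNSLSHPPPD"
        assert window.mutant_seq == "FSIVRTSLSHPPPD"
        assert window.mutated_offset == 6
        assert window.synthesis_seq == "FSIVRTSLSHPPPDC"

    def test_centered_policy(self):
        rec = embed_record("FSIVRNSLSHPPPD", at=21)
        change = ProteinChange("N", 26, "T")
        window = design_window(rec, change, length=14)
        # mutated residue at ceil(14/2) = offset 7
        assert window.mutated_offset == 7
        assert window.window_start == 20

    def test_left_clamping_at_terminus(self):
        rec = ProteinRecord("P1", "G1", repeat_seq(30))
        change = ProteinChange(rec.sequence[0], 1, "W")
        window = design_window(rec, change, length=14)
        assert window.window_start == 1 and window.mutated_offset == 1

    def test_right_clamping_at_terminus(self):
        rec = ProteinRecord("P1", "G1", repeat_seq(30))
        change = ProteinChange(rec.sequence[29], 30, "A" if rec.sequence[29] != "A" else "C")
        window = design_window(rec, change, length=14)
        assert window.window_start == 17 and window.mutated_offset == 14

    def test_reference_mismatch_is_hard_error(self):
        rec = ProteinRecord("P1", "G1", repeat_seq(30))
        wrong = "W" if rec.sequence[9] != "W" else "Y"
        with pytest.raises(DesignError, match="mismatch"):
            design_window(rec, ProteinChange(wrong, 10, "A"), length=14)

    def test_window_longer_than_protein_is_hard_error(self):
        rec = ProteinRecord("P1", "G1", repeat_seq(10))
        with pytest.raises(DesignError, match="length"):
            design_window(rec, ProteinChange(rec.sequence[4], 5, "W"), length=14)

    def test_tag_can_be_disabled(self):
        rec = ProteinRecord("P1", "G1", repeat_seq(30))
        change = ProteinChange(rec.sequence[14], 15, "W")
        window = design_window(rec, change, add_tag=False)
        assert window.synthesis_seq == window.mutant_seq

    def test_cysteine_warning_flag(self):
        rec = embed_record("ACDEFGHIKLMNPQ", at=1, total=30)
        change = ProteinChange("D", 3, "W")
        window = design_window(rec, change, length=14, window_start=1)
        assert "cysteine_in_window" in window.flags

    def test_boundary_crossing_flag(self):
        rec = ProteinRecord(
            "P1",
            "G1",
            repeat_seq(60),
            features=(TopologyFeature("extracellular", 1, 10),),
        )
        change = ProteinChange(rec.sequence[7], 8, "W" if rec.sequence[7] != "W" else "Y")
        window = design_window(rec, change, length=14)
        assert "crosses_feature_boundary" in window.flags

    @given(
        length=st.integers(min_value=1, max_value=20),
        pos=st.integers(min_value=1, max_value=80),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_window_invariants_hold(self, length, pos, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(AA20), size=80))
        rec = ProteinRecord("P1", "G1", seq)
        ref = seq[pos - 1]
        alt = AA20[(AA20.index(ref) + 1) % 20]
        window = design_window(rec, ProteinChange(ref, pos, alt), length=length)
        # substring oracle: re-extract the wild-type window from the protein
        assert (
            window.wildtype_seq
            == seq[window.window_start - 1 : window.window_start - 1 + length]
        )
        assert len(window.wildtype_seq) == len(window.mutant_seq) == length
        diffs = [
            i
            for i, (a, b) in enumerate(zip(window.wildtype_seq, window.mutant_seq))
            if a != b
        ]
        assert diffs == [window.mutated_offset - 1]
        assert window.mutant_seq[window.mutated_offset - 1] == alt
        assert window.wildtype_seq[window.mutated_offset - 1] == ref
        assert window.synthesis_seq == window.mutant_seq + "C"
        report = validate_pair(window.wildtype_seq, window.mutant_seq)
        assert report.passed and report.offset == window.mutated_offset


def surface_store(n_genes):
    records = []
    for i in range(n_genes):
        records.append(
            ProteinRecord(
                f"S{i:03d}",
                f"Surf{i:03d}",
                repeat_seq(100),
                features=(TopologyFeature("extracellular", 1, 100),),
                location_labels=frozenset({"plasma_membrane"}),
            )
        )
    return AnnotationStore(records)


def msp_calls_for(store, genes_positions):
    variants = []
    for gene, pos in genes_positions:
        rec = store.resolve(gene)
        ref = rec.sequence[pos - 1]
        alt = "A" if ref != "A" else "C"
        variants.append(MissenseVariant("S1", gene, ProteinChange(ref, pos, alt)))
    calls, _ = classify_cohort(variants, store)
    return calls


class TestSelectPanel:
    def test_truncation_to_n(self):
        store = surface_store(12)
        calls = msp_calls_for(store, [(f"Surf{i:03d}", 10) for i in range(12)])
        panel = select_panel(calls, store, n=10)
        assert len(panel.targets) == 10 and not panel.shortfall
        assert sum(1 for _, r in panel.excluded if r == "rank_overflow") == 2

    def test_one_call_per_gene(self):
        store = surface_store(10)
        pairs = [("Surf000", p) for p in (30, 10, 20)] + [
            (f"Surf{i:03d}", 10) for i in range(1, 10)
        ]
        panel = select_panel(msp_calls_for(store, pairs), store, n=10)
        genes = [c.variant.gene_symbol for c, _ in panel.targets]
        assert len(genes) == len(set(genes)) == 10
        chosen = next(c for c, _ in panel.targets if c.variant.gene_symbol == "Surf000")
        assert chosen.variant.change.position == 10  # lowest position wins

    def test_exclude_genes_promotes_next(self):
        store = surface_store(11)
        calls = msp_calls_for(store, [(f"Surf{i:03d}", 10) for i in range(11)])
        panel = select_panel(calls, store, n=10, exclude_genes=["Surf000"])
        genes = {c.variant.gene_symbol for c, _ in panel.targets}
        assert "Surf000" not in genes and "Surf010" in genes

    def test_shortfall_warning(self):
        store = surface_store(3)
        calls = msp_calls_for(store, [(f"Surf{i:03d}", 10) for i in range(3)])
        panel = select_panel(calls, store, n=10)
        assert panel.shortfall and len(panel.targets) == 3

    def test_extracellular_ranked_before_secreted(self):
        records = [
            ProteinRecord(
                "SEC1",
                "Asecr",  # alphabetically first, but secreted-reason
                repeat_seq(100),
                features=(),
                location_labels=frozenset({"secreted"}),
            ),
            ProteinRecord(
                "EXT1",
                "Zmemb",
                repeat_seq(100),
                features=(TopologyFeature("extracellular", 1, 100),),
                location_labels=frozenset({"plasma_membrane"}),
            ),
        ]
        store = AnnotationStore(records)
        calls = msp_calls_for(store, [("Asecr", 50), ("Zmemb", 50)])
        panel = select_panel(calls, store, n=1)
        assert panel.targets[0][0].variant.gene_symbol == "Zmemb"

    def test_determinism(self):
        store = surface_store(12)
        calls = msp_calls_for(store, [(f"Surf{i:03d}", 10) for i in range(12)])
        a = panel_manifest_frame(select_panel(calls, store, n=10))
        b = panel_manifest_frame(select_panel(list(reversed(calls)), store, n=10))
        assert a.to_csv() == b.to_csv()


class TestExportPanelFasta:
    def test_two_records_per_target(self, tmp_path):
        from Bio import SeqIO

        store = surface_store(10)
        calls = msp_calls_for(store, [(f"Surf{i:03d}", 10) for i in range(10)])
        panel = select_panel(calls, store, n=10)
        path = tmp_path / "panel.fasta"
        assert export_panel_fasta(panel, path) == 20
        records = list(SeqIO.parse(str(path), "fasta"))
        assert len(records) == 20
        mutants = [r for r in records if r.id.endswith("|mutant")]
        wildtypes = [r for r in records if r.id.endswith("|wildtype")]
        assert all(str(r.seq).endswith("C") for r in mutants)
        assert len(wildtypes) == 10

    def test_empty_panel_writes_empty_file(self, tmp_path):
        store = surface_store(1)
        panel = select_panel([], store, n=10)
        path = tmp_path / "empty.fasta"
        assert export_panel_fasta(panel, path) == 0
        assert path.read_text() == ""


class TestPoolCocktail:
    def test_ten_components(self):
        assert pool_cocktail([0.05] * 10) == pytest.approx(0.5)

    def test_empty_pool(self):
        assert pool_cocktail([]) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pool_cocktail([0.05, -0.01])
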