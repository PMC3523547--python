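import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surfscreen import Call, classify_localization, load_annotation_table, surface_probe_set
from surfscreen.annotation import classify_terms, load_overrides


def _evidence(rows):
    return pd.DataFrame(rows, columns=["subject", "compartment_term", "source"])


class TestLoadAnnotationTable:
    def test_duplicates_collapse_across_files(self, tmp_path):
        for name in ("a.tsv", "b.tsv"):
            (tmp_path / name).write_text(
                "subject\tcompartment_term\tsource\nG1\tplasma membrane\tGO\n"
            )
        merged = load_annotation_table([tmp_path / "a.tsv", tmp_path / "b.tsv"])
        assert len(merged) == 1

    def test_empty_file_list_gives_empty_collection(self):
        assert len(load_annotation_table([])) == 0

    def test_unknown_source_is_error(self, tmp_path):
        (tmp_path / "a.tsv").write_text(
            "subject\tcompartment_term\tsource\nG1\tplasma membrane\tWIKIPEDIA\n"
        )
        with pytest.raises(ValueError, match="WIKIPEDIA.*CURATION_OVERRIDE"):
            load_annotation_table([tmp_path / "a.tsv"])

    def test_generated_dataset_annotates_every_probe(self, small_dataset):
        assert set(small_dataset.evidence["subject"]) == set(
            small_dataset.matrix.probe_ids
        )


class TestClassifyLocalization:
    @pytest.mark.parametrize(
        "terms,expected",
        [
            # surface + another compartment is still surface
            (["plasma membrane", "Golgi apparatus"], Call.CELL_SURFACE),
            (["mitochondrial inner membrane"], Call.INTERNAL_MEMBRANE_ONLY),
            (["membrane"], Call.UNKNOWN_MEMBRANE),
            (["cytoplasm", "nucleus"], Call.NON_MEMBRANE),
            (["integral component of plasma membrane"], Call.CELL_SURFACE),
            (["nuclear envelope", "endoplasmic reticulum"], Call.INTERNAL_MEMBRANE_ONLY),
            (["PLASMA MEMBRANE"], Call.CELL_SURFACE),  # case-insensitive
            ([], Call.NON_MEMBRANE),
        ],
    )
    def test_precedence_rules(self, terms, expected):
        assert classify_terms(terms) is expected

    def test_override_dominates_evidence(self):
        evidence = _evidence([("G1", "plasma membrane", "GO")])
        call = classify_localization(
            "G1", evidence, overrides={"G1": Call.NON_MEMBRANE}
        )
        assert call.call is Call.NON_MEMBRANE
        assert call.decided_by == "CURATION_OVERRIDE"

    def test_supporting_terms_reported(self):
        evidence = _evidence(
            [("G1", "plasma membrane", "GO"), ("G1", "Golgi apparatus", "GO")]
        )
        call = classify_localization("G1", evidence)
        assert call.call is Call.CELL_SURFACE
        assert call.supporting_terms == ["plasma membrane"]

    @given(
        terms=st.lists(
            st.sampled_from(
                [
                    "plasma membrane",
                    "cell surface",
                    "mitochondrial membrane",
                    "Golgi apparatus",
                    "endoplasmic reticulum",
                    "membrane",
                    "cytoplasm",
                    "nucleolus",
                ]
            ),
            max_size=6,
        ),
        seed=st.randoms(use_true_random=False),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_call_is_order_independent_and_monotone(self, terms, seed):
        baseline = classify_terms(terms)
        shuffled = list(terms)
        seed.shuffle(shuffled)
        assert classify_terms(shuffled) is baseline
        # adding a surface term never demotes
        assert classify_terms([*terms, "plasma membrane"]) is Call.CELL_SURFACE

    def test_load_overrides_rejects_unknown_call(self, tmp_path):
        (tmp_path / "o.tsv").write_text("subject\tcall\nG1\tMAYBE_SURFACE\n")
        with pytest.raises(ValueError, match="unknown call"):
            load_overrides(tmp_path / "o.tsv")


class TestSurfaceProbeSet:
    def test_all_non_membrane_gives_empty_set(self):
        calls = {"P1": Call.NON_MEMBRANE, "P2": Call.NON_MEMBRANE}
        assert surface_probe_set(["P1", "P2"], None, calls) == []

    def test_gene_level_call_fans_out_to_probes(self):
        calls = {"GENE1": Call.CELL_SURFACE}
        mapping = {"P1": "GENE1", "P2": "GENE1", "P3": "GENE2"}
        assert surface_probe_set(["P1", "P2", "P3"], mapping, calls) == ["P1", "P2"]

    def test_unknown_membrane_only_with_flag(self):
        calls = {"P1": Call.UNKNOWN_MEMBRANE, "P2": Call.CELL_SURFACE}
        assert surface_probe_set(["P1", "P2"], None, calls) == ["P2"]
        assert surface_probe_set(["P1", "P2"], None, calls, include_unknown=True) == [
            "P1",
            "P2",
        ]

    def test_generator_surface_count_matches_ground_truth(self, small_dataset):
        from surfscreen.annotation import classify_all

        truth = small_dataset.truth
        calls = classify_all(small_dataset.evidence)
        surface = surface_probe_set(small_dataset.matrix.probe_ids, None, calls)
        expected = {p for p, is_surface in truth.surface_labels.items() if is_surface}
        assert set(surface) == expected
        assert len(surface) == math.ceil(
            small_dataset.config.surface_fraction * small_dataset.config.n_probes
        )

    def test_planted_probes_all_pass_surface_filter(self, small_dataset):
        from surfscreen.annotation import classify_all

        calls = classify_all(small_dataset.evidence)
        surface = set(
            surface_probe_set(small_dataset.matrix.probe_ids, None, calls)
        )
        for disease in small_dataset.truth.planted:
            assert small_dataset.truth.planted_probes(disease) <= surface
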