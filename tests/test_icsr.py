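"""Data model: catalog, dictionary, line-listing I/O, aggregation."""

import datetime as dt
import io

import pytest
from hypothesis import given, strategies as st

from quinpv.icsr import (
    CountTable,
    DictionaryError,
    DrugLookupError,
    LineListingError,
    QUINOLONE_CATALOG,
    SocCategory,
    SocGroup,
    aggregate_counts,
    classify_generation,
    classify_icsr_soc_group,
    map_pt_to_soc,
    read_line_listing,
    write_line_listing,
)

from conftest import make_icsr, random_listing


class TestCatalog:
    @pytest.mark.parametrize(
        "name,generation",
        [
            ("nalidixic acid", 1), ("cinoxacin", 1), ("flumequine", 1),
            ("ciprofloxacin", 2), ("norfloxacin", 2), ("enoxacin", 2),
            ("levofloxacin", 3), ("moxifloxacin", 3), ("pefloxacin", 3),
            ("prulifloxacin", 4),
            ("Ciprofloxacin ", 2),  # normalization: case + trailing space
            ("  LEVOFLOXACIN", 3),
        ],
    )
    def test_generation_lookup(self, name, generation):
        assert classify_generation(name) == generation

    def test_unknown_drug_raises_with_name(self):
        with pytest.raises(DrugLookupError, match="amoxicillin"):
            classify_generation("amoxicillin")

    def test_catalog_is_a_partition(self):
        assert len(QUINOLONE_CATALOG) == 14
        by_gen = {g: 0 for g in (1, 2, 3, 4)}
        for entry in QUINOLONE_CATALOG.values():
            by_gen[entry.generation] += 1
        assert by_gen == {1: 4, 2: 6, 3: 3, 4: 1}


class TestDictionary:
    @pytest.mark.parametrize(
        "pt,soc",
        [
            ("Tremor", SocCategory.NERVOUS),
            ("tendinitis", SocCategory.MUSCULOSKELETAL),
            ("Insomnia", SocCategory.PSYCHIATRIC),
            ("peripheral  neuropathy", SocCategory.NERVOUS),  # whitespace collapsed
            ("nausea", SocCategory.OTHER),  # unlisted
        ],
    )
    def test_map_pt_to_soc(self, pt_dict, pt, soc):
        assert map_pt_to_soc(pt, pt_dict) is soc

    def test_empty_term_rejected(self, pt_dict):
        with pytest.raises(DictionaryError):
            map_pt_to_soc("  ", pt_dict)

    def test_case_series_terms_resolve(self, pt_dict):
        """Every term of the regional case series maps to its SOC."""
        nervous = [
            "tremor", "paraesthesia", "headache", "syncope", "pre-syncope",
            "formication", "dizziness", "ageusia", "memory loss", "anosmia",
            "epilepsy", "altered state of consciousness", "metallic taste",
            "paralysis", "peripheral neuropathy",
            "decreased level of consciousness", "sudden fall", "hypotonia",
            "afasia", "drowsiness", "akathisia", "burning sensation",
            "cerebral ischemia", "balance disorder", "hemiparesis",
        ]
        musculoskeletal = [
            "myalgia", "arthralgia", "tendinitis", "limb pain", "tendon pain",
            "musculoskeletal pain", "rhabdomyolysis", "arthromyalgia",
            "hypercreatininemia", "muscle rigidity", "muscle tension",
            "muscle inflammation", "muscle weakness",
        ]
        psychiatric = [
            "insomnia", "hallucination", "confusional state", "agitation",
            "temporospatial disorientation", "restlessness", "irritability",
            "acute psychosis", "anxiety", "drug abuse", "dyssomnia",
            "mood swing", "auditory hallucination", "mental disorder",
            "psychotic disorder", "panic attack",
        ]
        for pt in nervous:
            assert map_pt_to_soc(pt, pt_dict) is SocCategory.NERVOUS, pt
        for pt in musculoskeletal:
            assert map_pt_to_soc(pt, pt_dict) is SocCategory.MUSCULOSKELETAL, pt
        for pt in psychiatric:
            assert map_pt_to_soc(pt, pt_dict) is SocCategory.PSYCHIATRIC, pt


class TestReader:
    def test_rows_merge_by_report_id(self, pt_dict):
        csv = (
            "report_id,receive_date,drug,preferred_term\n"
            "C-001,2018-06-01,ciprofloxacin,tremor\n"
            "C-001,2018-06-01,ciprofloxacin,myalgia\n"
        )
        (icsr,) = read_line_listing(io.StringIO(csv), pt_dict)
        assert len(icsr.events) == 2
        assert {e.soc for e in icsr.events} == {
            SocCategory.NERVOUS, SocCategory.MUSCULOSKELETAL,
        }

    def test_empty_file_with_header(self, pt_dict):
        csv = "report_id,receive_date,drug,preferred_term\n"
        assert read_line_listing(io.StringIO(csv), pt_dict) == []

    def test_six_row_fixture(self, six_row_icsrs):
        assert len(six_row_icsrs) == 3
        by_id = {r.report_id: r for r in six_row_icsrs}
        levo = by_id["C-002"]
        assert levo.suspects[0].drug.generation == 3
        socs = {e.preferred_term: e.soc for e in levo.events}
        assert socs["tendinitis"] is SocCategory.MUSCULOSKELETAL
        assert socs["nausea"] is SocCategory.OTHER

    def test_missing_required_column(self, pt_dict):
        csv = "report_id,receive_date,preferred_term\nC-1,2018-01-01,tremor\n"
        with pytest.raises(LineListingError, match="drug"):
            read_line_listing(io.StringIO(csv), pt_dict)

    def test_duplicate_row_rejected(self, pt_dict):
        csv = (
            "report_id,receive_date,drug,preferred_term,onset_date\n"
            "C-1,2018-01-01,ciprofloxacin,tremor,2018-01-01\n"
            "C-1,2018-01-01,ciprofloxacin,tremor,2018-01-01\n"
        )
        with pytest.raises(LineListingError, match="duplicate"):
            read_line_listing(io.StringIO(csv), pt_dict)

    def test_bad_date_names_line(self, pt_dict):
        csv = (
            "report_id,receive_date,drug,preferred_term\n"
            "C-1,01/02/2018,ciprofloxacin,tremor\n"
        )
        with pytest.raises(LineListingError, match="line 2"):
            read_line_listing(io.StringIO(csv), pt_dict)

    def test_unknown_drug_strict_vs_permissive(self, pt_dict):
        csv = (
            "report_id,receive_date,drug,preferred_term\n"
            "C-1,2018-01-01,amoxicillin,tremor\n"
            "C-2,2018-01-01,ciprofloxacin,tremor\n"
        )
        with pytest.raises(DrugLookupError):
            read_line_listing(io.StringIO(csv), pt_dict)
        kept = read_line_listing(io.StringIO(csv), pt_dict, permissive=True)
        assert [r.report_id for r in kept] == ["C-2"]

    def test_study_window_filters_on_receive_date(self, pt_dict):
        csv = (
            "report_id,receive_date,drug,preferred_term\n"
            "C-1,2001-06-01,ciprofloxacin,tremor\n"
            "C-2,2005-06-01,ciprofloxacin,tremor\n"
        )
        window = (dt.date(2002, 1, 1), dt.date(2019, 3, 31))
        kept = read_line_listing(io.StringIO(csv), pt_dict, study_window=window)
        assert [r.report_id for r in kept] == ["C-2"]

    def test_roundtrip_is_stable(self, six_row_icsrs, pt_dict):
        buf = io.StringIO()
        write_line_listing(six_row_icsrs, buf)
        first = buf.getvalue()
        again = read_line_listing(io.StringIO(first), pt_dict)
        buf2 = io.StringIO()
        write_line_listing(again, buf2)
        assert buf2.getvalue() == first


class TestAggregation:
    def test_single_icsr_counts(self, pt_dict):
        icsr = make_icsr("A-1", ["levofloxacin"], ["tremor", "myalgia"], pt_dict)
        table = aggregate_counts([icsr], level="generation")
        assert table.count("gen3", SocCategory.NERVOUS) == 1
        assert table.count("gen3", SocCategory.MUSCULOSKELETAL) == 1
        assert table.total("gen3") == 2
        assert table.total("total") == 2

    def test_multi_suspect_attributes_to_each_drug(self, pt_dict):
        icsr = make_icsr(
            "A-2", ["levofloxacin", "ciprofloxacin"], ["tremor"], pt_dict
        )
        table = aggregate_counts([icsr], level="drug")
        assert table.count("levofloxacin", SocCategory.NERVOUS) == 1
        assert table.count("ciprofloxacin", SocCategory.NERVOUS) == 1
        assert table.total("total") == 2

    def test_per_report_attribution_counts_once_per_generation(self, pt_dict):
        icsr = make_icsr(
            "A-3", ["levofloxacin", "moxifloxacin"], ["tremor"], pt_dict
        )
        table = aggregate_counts([icsr], level="generation", attribution="per_report")
        assert table.count("gen3", SocCategory.NERVOUS) == 1
        assert table.total("total") == 1

    def test_zero_icsrs(self):
        table = aggregate_counts([], level="generation")
        assert table.total("total") == 0
        table.validate()

    @given(st.integers(0, 40), st.integers(0, 2**31 - 1))
    def test_conservation_against_brute_force(self, n, seed):
        import numpy as np
        from quinpv.icsr import load_pt_dictionary

        pt_dict = load_pt_dictionary()
        icsrs = random_listing(np.random.default_rng(seed), n, pt_dict)
        table = aggregate_counts(icsrs, level="drug")
        table.validate()
        # brute force: enumerate every (suspect, event) pair
        expected = sum(len(r.suspects) * len(r.events) for r in icsrs)
        assert table.total("total") == expected
        for soc in SocCategory:
            brute = sum(
                len(r.suspects) * sum(1 for e in r.events if e.soc is soc)
                for r in icsrs
            )
            assert table.count("total", soc) == brute


class TestSocGroup:
    @pytest.mark.parametrize(
        "pts,expected",
        [
            (["tremor", "headache"], SocGroup.NERVOUS),
            (["tremor", "myalgia"], SocGroup.MULTIPLE),
            (["nausea"], SocGroup.NONE),
            (["insomnia"], SocGroup.PSYCHIATRIC),
            (["myalgia", "nausea"], SocGroup.MUSCULOSKELETAL),
        ],
    )
    def test_classification(self, pt_dict, pts, expected):
        icsr = make_icsr("G-1", ["ciprofloxacin"], pts, pt_dict)
        assert classify_icsr_soc_group(icsr) is expected


class TestCountTableInvariants:
    def test_published_table_row_sums(self, table1):
        df = table1.df
        soc_cols = ["nervous", "musculoskeletal", "psychiatric", "other"]
        assert (df[soc_cols].sum(axis=1) == df["total"]).all()

    def test_published_table_generation_sum_matches_grand_total(self, table1):
        gens = table1.df[table1.df["level"] == "generation"]
        assert gens["total"].sum() == table1.total("total") == 21941

    def test_invalid_row_total_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            [{"group": "gen1", "level": "generation", "nervous": 1,
              "musculoskeletal": 0, "psychiatric": 0, "other": 0, "total": 5}]
        )
        with pytest.raises(ValueError, match="total"):
            CountTable(df).validate()
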