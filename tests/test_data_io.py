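import numpy as np
import pytest

from isoweb import (
    FoodWebInput,
    IsotopeMeasurement,
    SourceSummary,
    read_consumers,
    read_foodweb,
    read_sources,
    summarize_sources,
    write_consumers,
    write_foodweb,
    write_sources,
)
from isoweb.errors import (
    EmptyInputError,
    ParseError,
    SchemaError,
    ValidationError,
)
from .conftest import make_consumer


def _write(path, text):
    path.write_text(text)
    return path


class TestReadConsumers:
    def test_single_row(self, tmp_path):
        p = _write(tmp_path / "c.csv",
                   "sample_id,lake,zone,taxon,group,d13C,d15N\n"
                   "Tro1,El Sol,pelagic,O. mykiss,trout,-15.3,6.63\n")
        (m,) = read_consumers(p)
        assert m.sample_id == "Tro1"
        assert m.zone == "pelagic"
        assert m.d13C == -15.3 and m.d15N == 6.63

    def test_header_only_gives_empty_list(self, tmp_path):
        p = _write(tmp_path / "c.csv", "sample_id,lake,zone,taxon,group,d13C,d15N\n")
        assert read_consumers(p) == []

    def test_unknown_zone_rejected(self, tmp_path):
        p = _write(tmp_path / "c.csv",
                   "sample_id,lake,zone,taxon,group,d13C,d15N\n"
                   "a,L,benthic,t,g,-15,5\n")
        with pytest.raises(ValidationError, match="benthic"):
            read_consumers(p)

    def test_missing_column_named_in_error(self, tmp_path):
        p = _write(tmp_path / "c.csv", "sample_id,lake,zone,taxon,group,d13C\na,L,pelagic,t,g,-15\n")
        with pytest.raises(SchemaError, match="d15N"):
            read_consumers(p)

    def test_non_numeric_delta_reports_row(self, tmp_path):
        p = _write(tmp_path / "c.csv",
                   "sample_id,lake,zone,taxon,group,d13C,d15N\n"
                   "a,L,pelagic,t,g,-15,5\nb,L,pelagic,t,g,oops,5\n")
        with pytest.raises(ParseError, match="row 1"):
            read_consumers(p)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = _write(tmp_path / "c.csv",
                   "sample_id,lake,zone,taxon,group,d13C,d15N\n"
                   "a,L,pelagic,t,g,-15,5\na,L,pelagic,t,g,-16,5\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_consumers(p)

    def test_decimal_comma_normalized(self, tmp_path):
        p = _write(tmp_path / "c.csv",
                   "sample_id,lake,zone,taxon,group,d13C,d15N\n"
                   'a,L,pelagic,t,g,"-17,04","0,11"\n')
        (m,) = read_consumers(p)
        assert m.d13C == pytest.approx(-17.04)
        assert m.d15N == pytest.approx(0.11)


class TestRoundTrips:
    def test_consumers_roundtrip_full_precision(self, tmp_path):
        ms = [make_consumer("a", -15.123456789, 6.987654321),
              make_consumer("b", -21.0, 3.5, zone="littoral")]
        write_consumers(ms, tmp_path / "c.csv")
        back = read_consumers(tmp_path / "c.csv")
        assert [(m.sample_id, m.d13C, m.d15N, m.zone) for m in back] == [
            (m.sample_id, m.d13C, m.d15N, m.zone) for m in ms
        ]

    def test_sources_roundtrip(self, tmp_path):
        srcs = [SourceSummary("Daphnia", "pelagic", -21.05, 0.1, 3.46, 0.2, 4)]
        write_sources(srcs, tmp_path / "s.csv")
        (s,) = read_sources(tmp_path / "s.csv")
        assert s == srcs[0]

    def test_foodweb_roundtrip_identical_matrix(self, tmp_path):
        web = FoodWebInput(
            ["alga", "grazer", "pred"],
            np.array([[0, 1, 0], [0, 0, 1], [0, 0, 0]]),
            {n: {"zone": "littoral", "guild": "bmi", "species_richness": 2}
             for n in ("alga", "grazer", "pred")},
        )
        write_foodweb(web, tmp_path / "m.csv", tmp_path / "a.csv")
        back = read_foodweb(tmp_path / "m.csv", tmp_path / "a.csv")
        assert back.node_names == web.node_names
        assert (back.adjacency == web.adjacency).all()
        assert back.node_attrs["alga"]["species_richness"] == 2


class TestReadFoodweb:
    def test_minimal_two_node_web(self, tmp_path):
        p = _write(tmp_path / "m.csv", ",alga,grazer\nalga,0,1\ngrazer,0,0\n")
        web = read_foodweb(p)
        assert web.adjacency.sum() == 1
        assert web.prey_of("grazer") == ["alga"]

    def test_chain_has_two_links(self, tmp_path):
        p = _write(tmp_path / "m.csv",
                   ",a,b,c\na,0,1,0\nb,0,0,1\nc,0,0,0\n")
        assert read_foodweb(p).adjacency.sum() == 2

    def test_non_square_rejected(self, tmp_path):
        p = _write(tmp_path / "m.csv", ",a,b\na,0,1\n")
        with pytest.raises(SchemaError, match="square"):
            read_foodweb(p)

    def test_fractional_entry_rejected(self, tmp_path):
        p = _write(tmp_path / "m.csv", ",a,b\na,0,0.5\nb,0,0\n")
        with pytest.raises(ValidationError, match="0.5"):
            read_foodweb(p)

    def test_entry_two_rejected(self):
        with pytest.raises(ValidationError):
            FoodWebInput(["a", "b"], np.array([[0, 2], [0, 0]]))

    def test_attr_orphans_listed(self, tmp_path):
        m = _write(tmp_path / "m.csv", ",a,b\na,0,1\nb,0,0\n")
        a = _write(tmp_path / "a.csv",
                   "node,zone,guild,species_richness\na,pelagic,fish,1\nc,pelagic,fish,1\n")
        with pytest.raises(SchemaError, match="orphans"):
            read_foodweb(m, a)


class TestSummarizeSources:
    def test_hand_mean_and_sd(self):
        ms = [make_consumer("a", -12.0, 1.0), make_consumer("b", -13.0, 1.4)]
        (s,) = summarize_sources(ms, group_by="group")
        assert s.mean_d13C == pytest.approx(-12.5)
        assert s.sd_d13C == pytest.approx(np.sqrt(0.5), abs=1e-9)  # ~0.707
        assert s.n == 2

    def test_singleton_group_sd_zero(self):
        (s,) = summarize_sources([make_consumer("a", -12.0, 1.0)])
        assert s.sd_d13C == 0.0 and s.sd_d15N == 0.0 and s.n == 1

    def test_group_by_lake(self):
        ms = [make_consumer("a", -12, 1, lake="X"), make_consumer("b", -20, 2, lake="Y")]
        out = summarize_sources(ms, group_by="lake")
        assert [s.name for s in out] == ["X", "Y"]

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInputError):
            summarize_sources([])

    def test_mean_preserved_under_reexpansion(self):
        ms = [make_consumer(f"s{i}", v, v / 2) for i, v in enumerate((-12.0, -13.0, -14.5))]
        (s,) = summarize_sources(ms)
        assert s.mean_d13C * s.n == pytest.approx(sum(m.d13C for m in ms))
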