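"""PED/MAP I/O, visit tables, trio assembly and the results report."""

import numpy as np
import pandas as pd
import pytest

from longimap.estimator import GeneFit
from longimap.ldmodel import ModelParams
from longimap.pedio import (MarkerPanel, extract_trios, read_ped_map,
                            read_visits, visits_to_status_table,
                            write_gene_results, write_ped_map)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadPedMap:
    def test_positions_echo_input(self, tiny_ped_map):
        panel, records = read_ped_map(*tiny_ped_map)
        assert list(panel.positions_cm) == [13.64, 14.68]
        assert panel.marker_ids == ["m1", "m2"]
        assert len(records) == 6

    def test_missing_genotype_code(self, tmp_path, tiny_ped_map):
        ped = write_lines(tmp_path / "m.ped", [
            "F1 p1 0 0 1 0  0 0  C T",
            "F1 p2 0 0 2 0  A G  C C",
        ])
        panel, records = read_ped_map(ped, tiny_ped_map[1])
        assert records[0].genotypes[0] is None
        assert records[0].genotypes[1] == ("C", "T")

    def test_minor_allele_target_rule(self, tiny_ped_map):
        panel, _ = read_ped_map(*tiny_ped_map)
        # among founders, G appears 1/8 times at m1 -> minor -> target
        assert panel.target_allele[0] == "G"

    def test_explicit_target_rule(self, tiny_ped_map):
        panel, _ = read_ped_map(*tiny_ped_map,
                                target_rule={"m1": "A", "m2": "C"})
        assert panel.target_allele == ["A", "C"]

    def test_ragged_ped_row_errors(self, tmp_path, tiny_ped_map):
        ped = write_lines(tmp_path / "bad.ped", ["F1 p1 0 0 1 0  A A  C"])
        with pytest.raises(ValueError, match="bad.ped:1"):
            read_ped_map(ped, tiny_ped_map[1])

    def test_non_biallelic_marker_errors(self, tmp_path, tiny_ped_map):
        ped = write_lines(tmp_path / "tri.ped", [
            "F1 p1 0 0 1 0  A A  C T",
            "F1 p2 0 0 2 0  A G  C G",
        ])
        with pytest.raises(ValueError, match="m2"):
            read_ped_map(ped, tiny_ped_map[1])

    def test_unsorted_map_resorted_with_warning(self, tmp_path):
        map_path = write_lines(tmp_path / "u.map", [
            "1\tm2\t14.68\t200",
            "1\tm1\t13.64\t100",
        ])
        ped = write_lines(tmp_path / "u.ped", [
            "F1 p1 0 0 1 0  C T  A A",
            "F1 p2 0 0 2 0  C C  A G",
        ])
        with pytest.warns(UserWarning, match="re-sorting"):
            panel, records = read_ped_map(ped, map_path)
        assert panel.marker_ids == ["m1", "m2"]
        assert records[0].genotypes[0] == ("A", "A")  # genotypes follow the sort

    def test_round_trip(self, tmp_path, tiny_ped_map):
        panel, records = read_ped_map(*tiny_ped_map)
        write_ped_map(panel, records, tmp_path / "rt.ped", tmp_path / "rt.map")
        panel2, records2 = read_ped_map(tmp_path / "rt.ped", tmp_path / "rt.map")
        assert panel2.marker_ids == panel.marker_ids
        assert np.allclose(panel2.positions_cm, panel.positions_cm)
        for a, b in zip(records, records2):
            assert a.genotypes == b.genotypes and a.subject_id == b.subject_id


class TestVisits:
    def test_basic_rows(self, tmp_path):
        p = write_lines(tmp_path / "v.tsv", ["S1\t1\t1", "S1\t2\t0", "S2\t1\tNA"])
        df = read_visits(p)
        table = visits_to_status_table(df)
        assert table["S1"] == (1, 0)
        assert table["S2"] == (None, None)

    def test_duplicate_pair_errors(self, tmp_path):
        p = write_lines(tmp_path / "d.tsv", ["S1\t1\t1", "S1\t1\t0"])
        with pytest.raises(ValueError, match="duplicate"):
            read_visits(p)

    def test_invalid_status_errors(self, tmp_path):
        p = write_lines(tmp_path / "i.tsv", ["S1\t1\t2"])
        with pytest.raises(ValueError, match="status"):
            read_visits(p)

    def test_four_visit_vector(self, tmp_path):
        p = write_lines(tmp_path / "f.tsv",
                        [f"S1\t{l}\t{s}" for l, s in zip(range(1, 5), "0011")])
        assert visits_to_status_table(read_visits(p))["S1"] == (0, 0, 1, 1)


def _panel():
    return MarkerPanel(["m1"], [0.0], [("A", "G")], ["A"])


def _rec(fam, sid, fid="0", mid="0", gt=("A", "G")):
    from longimap.pedio import PedigreeRecord
    return PedigreeRecord(fam, sid, fid, mid, "0", [gt])


class TestExtractTrios:
    def test_siblings_share_parents(self):
        recs = [_rec("F1", "dad"), _rec("F1", "mom")] + \
               [_rec("F1", f"k{i}", "dad", "mom") for i in range(3)]
        phen = {f"k{i}": (1,) for i in range(3)}
        trios, n_fam, n_excl = extract_trios(recs, phen, _panel())
        assert len(trios) == 3 and n_fam == 1 and n_excl == 0
        assert len({t.family_index for t in trios}) == 1

    def test_offspring_without_phenotype_excluded_and_counted(self):
        recs = [_rec("F1", "dad"), _rec("F1", "mom"),
                _rec("F1", "k1", "dad", "mom"), _rec("F1", "k2", "dad", "mom")]
        trios, _, n_excl = extract_trios(recs, {"k1": (1,)}, _panel())
        assert [t.offspring_id for t in trios] == ["k1"]
        assert n_excl == 1

    def test_family_count_indexing(self):
        recs = []
        phen = {}
        for i in range(138):
            recs += [_rec(f"F{i}", f"d{i}"), _rec(f"F{i}", f"m{i}"),
                     _rec(f"F{i}", f"k{i}", f"d{i}", f"m{i}")]
            phen[f"k{i}"] = (0,)
        trios, n_fam, _ = extract_trios(recs, phen, _panel())
        assert n_fam == 138
        assert sorted({t.family_index for t in trios}) == list(range(1, 139))

    def test_missing_parent_placeholder_kept(self):
        # father referenced but absent from the records: trio kept with
        # all-missing father genotypes
        recs = [_rec("F1", "mom"), _rec("F1", "k1", "ghost", "mom")]
        trios, _, _ = extract_trios(recs, {"k1": (1,)}, _panel())
        assert trios[0].father_counts[0] == -1
        assert trios[0].mother_counts[0] >= 0

    def test_own_ancestor_cycle_errors(self):
        recs = [_rec("F1", "k1", "k1", "0")]
        with pytest.raises(ValueError, match="own"):
            extract_trios(recs, {"k1": (1,)}, _panel())

    def test_non_nuclear_family_rejected(self):
        recs = [_rec("F1", "dad"), _rec("F1", "mom"),
                _rec("F1", "k1", "dad", "mom"),
                _rec("F1", "gk", "k1", "mom2")]
        with pytest.raises(ValueError, match="nuclear"):
            extract_trios(recs, {"k1": (1,), "gk": (1,)}, _panel())

    def test_never_more_trios_than_offspring(self, demo_sim):
        recs = demo_sim._records()
        phen = demo_sim.status_table()
        trios, _, n_excl = extract_trios(recs, phen, demo_sim.panel())
        n_offspring = sum(1 for r in recs if r.father_id != "0")
        assert len(trios) + n_excl <= n_offspring


class TestResultsReport:
    def _fit(self, gene="G1", converged=True):
        return GeneFit(gene=gene, params=ModelParams(1.234567891, 50, 0.654321, 0.1),
                       se_tau=0.0123456789, se_c=0.02, p_value_c=1.5e-7,
                       n_trios_affected=100, n_trios_unaffected=50,
                       converged=converged)

    def test_round_trip_six_significant_digits(self, tmp_path):
        path = tmp_path / "res.tsv"
        write_gene_results([self._fit()], path)
        df = pd.read_csv(path, sep="\t")
        assert df.loc[0, "gene"] == "G1"
        assert df.loc[0, "tau_hat"] == pytest.approx(1.234567891, rel=1e-9)
        assert df.loc[0, "se_tau"] == pytest.approx(0.0123456789, rel=1e-6)
        assert df.loc[0, "p_value"] == pytest.approx(1.5e-7, rel=1e-6)
        assert df.loc[0, "n_trios"] == 150

    def test_non_converged_row_has_empty_se(self, tmp_path):
        path = tmp_path / "res.tsv"
        write_gene_results([self._fit(converged=False)], path)
        df = pd.read_csv(path, sep="\t")
        assert df.loc[0, "converged"] == False  # noqa: E712
        assert np.isnan(df.loc[0, "se_tau"]) and np.isnan(df.loc[0, "p_value"])

    def test_empty_fits_error(self, tmp_path):
        with pytest.raises(ValueError):
            write_gene_results([], tmp_path / "x.tsv")
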