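import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

import epiwalsh as ew
from epiwalsh import (
    GenotypePhenotypeMap,
    IncompleteMapError,
    MapError,
    Site,
    read_map,
    walsh_encode,
    write_map,
    wyk_encode,
)
from epiwalsh.linear import decompose

from conftest import binary_genotypes, binary_map


class TestMapValidation:
    def test_toy_map_structure(self, toy_map):
        assert toy_map.n_sites == 2
        assert toy_map.wildtype == "00"
        assert toy_map.n_genotypes == 4
        np.testing.assert_array_equal(toy_map.phenotypes, [0, 2, 1, 2])

    def test_missing_genotype_named_in_error(self):
        with pytest.raises(IncompleteMapError, match="11"):
            GenotypePhenotypeMap.from_arrays(["00", "01", "10"], [0, 2, 1])

    def test_duplicate_genotype_rejected(self):
        with pytest.raises(MapError, match="duplicate"):
            GenotypePhenotypeMap.from_arrays(
                ["00", "01", "10", "10"], [0, 2, 1, 2]
            )

    def test_negative_stdev_rejected(self):
        with pytest.raises(MapError, match="negative stdev"):
            GenotypePhenotypeMap.from_arrays(
                ["0", "1"], [0, 1], stdevs=[0.1, -0.1]
            )

    def test_five_site_map_has_32_records(self):
        m = binary_map(5, np.arange(32.0))
        assert m.n_genotypes == 32

    def test_invalid_state_label_rejected(self):
        sites = [Site(0, ("0", "1"), "0")]
        rec = pd.DataFrame(
            {"genotype": ["0", "2"], "phenotype": [0.0, 1.0], "stdev": 0.0, "n": 1}
        )
        with pytest.raises(MapError, match="invalid"):
            GenotypePhenotypeMap(sites=sites, records=rec)

    def test_site_invariants(self):
        with pytest.raises(MapError):
            Site(0, ("A", "A"), "A")  # duplicate labels
        with pytest.raises(MapError):
            Site(0, ("A", "C"), "G")  # wildtype not a state
        with pytest.raises(MapError):
            Site(0, ("A",), "A")  # too few states


class TestWalshEncoding:
    @pytest.mark.parametrize("L", [2, 3, 4, 5])
    def test_full_design_is_hadamard(self, L):
        X = walsh_encode(binary_map(L, np.zeros(2**L))).matrix
        assert X.shape == (2**L, 2**L)
        np.testing.assert_array_equal(X.T @ X, 2**L * np.eye(2**L, dtype=int))

    def test_constant_column_first_and_order_tags(self):
        enc = walsh_encode(binary_map(5, np.zeros(32)))
        assert enc.labels[0] == ()
        np.testing.assert_array_equal(enc.matrix[:, 0], 1)
        counts = [int((enc.orders == k).sum()) for k in range(6)]
        assert counts == [comb(5, k) for k in range(6)]

    def test_truncation_counts(self):
        enc = walsh_encode(binary_map(5, np.zeros(32)), max_order=2)
        assert enc.matrix.shape == (32, 1 + 5 + 10)
        assert enc.orders.max() == 2

    def test_wildtype_row_is_all_minus_one_after_constant(self):
        m = binary_map(3, np.zeros(8))
        enc = walsh_encode(m)
        wt_row = enc.matrix[m.genotypes.index("000")]
        np.testing.assert_array_equal(wt_row[enc.orders == 1], -1)

    def test_four_state_site_redirects_to_wyk(self):
        sites = [Site(0, ("A", "C", "G", "T"), "G")]
        rec = pd.DataFrame(
            {
                "genotype": ["A", "C", "G", "T"],
                "phenotype": [0.0, 1.0, 2.0, 3.0],
                "stdev": 0.0,
                "n": 1,
            }
        )
        m = GenotypePhenotypeMap(sites=sites, records=rec)
        with pytest.raises(MapError, match="wyk_encode"):
            walsh_encode(m)

    def test_record_permutation_permutes_rows_and_preserves_coefficients(self, rng):
        phen = rng.normal(size=16)
        m = binary_map(4, phen)
        beta = decompose(m.phenotypes, walsh_encode(m)).values
        perm = rng.permutation(16)
        m2 = GenotypePhenotypeMap(
            sites=m.sites, records=m.records.iloc[perm].reset_index(drop=True)
        )
        beta2 = decompose(m2.phenotypes, walsh_encode(m2)).values
        np.testing.assert_allclose(beta2, beta, atol=1e-12)


def nucleotide_map():
    """Two 4-state sites + three binary sites: 128 genotypes."""
    states = [("A", "C", "G", "T"), ("A", "C", "G", "T"), ("0", "1"), ("0", "1"), ("0", "1")]
    wt = "GA000"
    genotypes = ["".join(c) for c in itertools.product(*states)]
    sites = [Site(i, s, wt[i]) for i, s in enumerate(states)]
    rec = pd.DataFrame(
        {
            "genotype": genotypes,
            "phenotype": np.arange(len(genotypes), dtype=float),
            "stdev": 0.0,
            "n": 1,
        }
    )
    return GenotypePhenotypeMap(sites=sites, records=rec)


class TestWykEncoding:
    def test_tetrahedral_codes_for_wildtype_g(self):
        site = Site(0, ("A", "C", "G", "T"), "G")
        rec = pd.DataFrame(
            {"genotype": list("GACT"), "phenotype": 0.0, "stdev": 0.0, "n": 1}
        )
        m = GenotypePhenotypeMap(sites=[site], records=rec)
        enc = wyk_encode(m)
        bits = enc.matrix[:, 1:4]  # order-1 bit columns, rows G,A,C,T
        np.testing.assert_array_equal(
            bits, [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]
        )

    def test_mixed_map_has_128_genotypes_and_orthogonal_full_design(self):
        m = nucleotide_map()
        assert m.n_genotypes == 128
        enc = wyk_encode(m)
        assert enc.matrix.shape == (128, 128)
        np.testing.assert_array_equal(
            enc.matrix.T @ enc.matrix, 128 * np.eye(128, dtype=int)
        )

    def test_all_binary_map_matches_walsh(self, rng):
        m = binary_map(4, rng.normal(size=16))
        w, y = walsh_encode(m), wyk_encode(m)
        np.testing.assert_array_equal(w.matrix, y.matrix)
        assert w.labels == y.labels

    def test_three_state_site_unsupported(self):
        m = GenotypePhenotypeMap(
            sites=[Site(0, ("A", "C", "G"), "A")],
            records=pd.DataFrame(
                {"genotype": list("ACG"), "phenotype": 0.0, "stdev": 0.0, "n": 1}
            ),
        )
        with pytest.raises(MapError, match="unsupported"):
            wyk_encode(m)


class TestIO:
    def test_json_round_trip_is_bit_exact(self, toy_map, tmp_path):
        path = write_map(toy_map, tmp_path / "toy.json")
        assert read_map(path) == toy_map

    def test_json_round_trip_simulated_five_site(self, rng, tmp_path):
        m = binary_map(5, rng.normal(size=32), stdevs=rng.uniform(0, 0.3, 32), n=3)
        path = write_map(m, tmp_path / "sim.json")
        assert read_map(path) == m

    def test_csv_round_trip(self, toy_map, tmp_path):
        path = write_map(toy_map, tmp_path / "toy.csv")
        m = read_map(path)
        assert m.genotypes == toy_map.genotypes
        np.testing.assert_array_equal(m.phenotypes, toy_map.phenotypes)
        assert m.wildtype == "00"

    def test_csv_multistate_round_trip_preserves_wildtype(self, tmp_path):
        m = nucleotide_map()
        path = write_map(m, tmp_path / "nt.csv")
        m2 = read_map(path)
        assert m2.wildtype == m.wildtype
        assert set(m2.genotypes) == set(m.genotypes)

    def test_locale_comma_decimals_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text('genotype,phenotype,stdev,n\n00,"1,5",0.0,3\n01,2.0,0.0,3\n10,1.0,0.0,3\n11,2.0,0.0,3\n')
        with pytest.raises(MapError):
            read_map(path)

    def test_json_missing_field_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"sites": [["0","1"]], "data": []}')
        with pytest.raises(MapError, match="wildtype"):
            read_map(path)

    def test_format_inferred_from_suffix(self, toy_map, tmp_path):
        write_map(toy_map, tmp_path / "m.json")
        write_map(toy_map, tmp_path / "m.csv")
        assert read_map(tmp_path / "m.json").n_genotypes == 4
        assert read_map(tmp_path / "m.csv").n_genotypes == 4
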