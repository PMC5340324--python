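"""Combinatorially complete genotype-phenotype maps: data model, encodings, I/O.

A genotype-phenotype map assigns a measured phenotype (with replicate
statistics) to every combination of states across a set of mutated sites.
This module provides the validated in-memory container
(:class:`GenotypePhenotypeMap`), the two ±1 design-matrix encodings used for
epistasis decomposition — the Walsh/Hadamard encoding for binary sites and
the WYK tetrahedral encoding for four-state (nucleotide) sites — and readers
and writers for a JSON dialect and flat CSV/TSV.

Conventions
-----------
* Genotype strings list per-site state labels with site 0 leftmost; binary
  maps use ``"0"`` (wild type) and ``"1"`` (mutant).
* Walsh encoding codes wild type as −1 and mutant as +1, so coefficients
  measure average effects relative to the geometric center of the map.
* Design columns are ordered: constant first, then interaction columns
  grouped by ascending order, lexicographic by site-index tuple within an
  order (and by bit-index tuple within a site tuple for tetrahedral sites).
"""

from __future__ import annotations

import csv
import io
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Site",
    "GenotypePhenotypeMap",
    "EncodedGenotypes",
    "MapError",
    "IncompleteMapError",
    "read_map",
    "write_map",
    "walsh_encode",
    "wyk_encode",
]


class MapError(ValueError):
    """Invalid genotype-phenotype map content."""


class IncompleteMapError(MapError):
    """The map does not contain every combination of site states."""


# Corners of the tetrahedron assigned, in order, to the non-wild-type states
# of a four-state site; the wild type is (1, 1, 1).
_TETRAHEDRON = ((1, -1, -1), (-1, 1, -1), (-1, -1, 1))


@dataclass(frozen=True)
class Site:
    """A mutated site with an ordered set of allowed state labels.

    Parameters
    ----------
    index : int
        0-based position of the site in the genotype string.
    states : tuple of str
        Ordered allowed state labels (two for binary sites, four for
        nucleotide sites).
    wildtype_state : str
        The wild-type label; must be one of ``states``.
    """

    index: int
    states: tuple[str, ...]
    wildtype_state: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if not 2 <= len(self.states) <= 4:
            raise MapError(
                f"site {self.index}: {len(self.states)} states; 2-4 supported"
            )
        if len(set(self.states)) != len(self.states):
            raise MapError(f"site {self.index}: duplicate state labels")
        if self.wildtype_state not in self.states:
            raise MapError(
                f"site {self.index}: wildtype {self.wildtype_state!r} "
                f"not among states {self.states}"
            )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def mutant_states(self) -> tuple[str, ...]:
        """Non-wild-type states, in the order they appear in ``states``."""
        return tuple(s for s in self.states if s != self.wildtype_state)


@dataclass
class GenotypePhenotypeMap:
    """A complete genotype-phenotype map with replicate phenotype statistics.

    ``records`` is a DataFrame with columns ``genotype`` (str),
    ``phenotype`` (mean over replicates), ``stdev`` (standard deviation,
    >= 0) and ``n`` (replicate count, >= 1). The map must be
    combinatorially complete: exactly one record per element of the
    Cartesian product of site states.
    """

    sites: list[Site]
    records: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)
        required = {"genotype", "phenotype", "stdev", "n"}
        missing_cols = required - set(self.records.columns)
        if missing_cols:
            raise MapError(f"records missing columns: {sorted(missing_cols)}")
        self._validate()

    def _validate(self) -> None:
        genotypes = self.records["genotype"].tolist()
        L = len(self.sites)
        for g in genotypes:
            if len(g) != L:
                raise MapError(f"genotype {g!r} has length {len(g)}, expected {L}")
            for site, label in zip(self.sites, g):
                if label not in site.states:
                    raise MapError(
                        f"genotype {g!r}: state {label!r} invalid at site "
                        f"{site.index} (allowed: {site.states})"
                    )
        seen = set()
        for g in genotypes:
            if g in seen:
                raise MapError(f"duplicate genotype {g!r}")
            seen.add(g)
        expected = {
            "".join(combo)
            for combo in itertools.product(*(s.states for s in self.sites))
        }
        absent = sorted(expected - seen)
        if absent:
            shown = ", ".join(absent[:8])
            more = "" if len(absent) <= 8 else f" (+{len(absent) - 8} more)"
            raise IncompleteMapError(f"incomplete map: missing {shown}{more}")
        if (self.records["stdev"] < 0).any():
            bad = self.records.loc[self.records["stdev"] < 0, "genotype"].iloc[0]
            raise MapError(f"negative stdev for genotype {bad!r}")
        if (self.records["n"] < 1).any():
            bad = self.records.loc[self.records["n"] < 1, "genotype"].iloc[0]
            raise MapError(f"replicate count < 1 for genotype {bad!r}")

    # -- convenience accessors -------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_genotypes(self) -> int:
        return len(self.records)

    @property
    def genotypes(self) -> list[str]:
        return self.records["genotype"].tolist()

    @property
    def phenotypes(self) -> np.ndarray:
        return self.records["phenotype"].to_numpy(dtype=float)

    @property
    def stdevs(self) -> np.ndarray:
        return self.records["stdev"].to_numpy(dtype=float)

    @property
    def n_replicates(self) -> np.ndarray:
        return self.records["n"].to_numpy(dtype=int)

    @property
    def wildtype(self) -> str:
        return "".join(s.wildtype_state for s in self.sites)

    @property
    def is_binary(self) -> bool:
        return all(s.n_states == 2 for s in self.sites)

    def wildtype_phenotype(self) -> float:
        idx = self.records.index[self.records["genotype"] == self.wildtype]
        return float(self.records.loc[idx[0], "phenotype"])

    def with_phenotypes(self, phenotypes: np.ndarray) -> "GenotypePhenotypeMap":
        """Copy of the map with the phenotype column replaced."""
        rec = self.records.copy()
        rec["phenotype"] = np.asarray(phenotypes, dtype=float)
        return GenotypePhenotypeMap(sites=self.sites, records=rec)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePhenotypeMap):
            return NotImplemented
        return self.sites == other.sites and self.records.equals(other.records)

    @classmethod
    def from_arrays(
        cls,
        genotypes: Sequence[str],
        phenotypes: Sequence[float],
        stdevs: Sequence[float] | float = 0.0,
        n: Sequence[int] | int = 1,
        wildtype: str | None = None,
    ) -> "GenotypePhenotypeMap":
        """Build a map from parallel arrays, inferring sites from genotypes.

        Per-site states are the sorted unique labels observed at that
        position. The wild type defaults to the all-``"0"`` genotype when
        every site uses labels ``0``/``1``, otherwise it must be given.
        """
        genotypes = list(genotypes)
        if not genotypes:
            raise MapError("no genotypes")
        L = len(genotypes[0])
        cols = [sorted({g[i] for g in genotypes if len(g) > i}) for i in range(L)]
        if wildtype is None:
            if all(set(c) <= {"0", "1"} for c in cols):
                wildtype = "0" * L
            else:
                raise MapError("wildtype must be given for non-0/1 state labels")
        sites = [
            Site(index=i, states=tuple(cols[i]), wildtype_state=wildtype[i])
            for i in range(L)
        ]
        G = len(genotypes)
        rec = pd.DataFrame(
            {
                "genotype": genotypes,
                "phenotype": np.asarray(phenotypes, dtype=float),
                "stdev": np.broadcast_to(np.asarray(stdevs, dtype=float), G).copy(),
                "n": np.broadcast_to(np.asarray(n, dtype=int), G).copy(),
            }
        )
        return cls(sites=sites, records=rec)


@dataclass
class EncodedGenotypes:
    """A ±1 design matrix for epistasis decomposition.

    ``matrix`` has one row per genotype (in map record order) and one column
    per model term. ``labels[c]`` is a tuple of ``(site_index, bit_index)``
    factors whose product forms column ``c`` (empty for the constant), and
    ``orders[c]`` is the number of distinct sites involved.
    """

    matrix: np.ndarray
    labels: tuple[tuple[tuple[int, int], ...], ...]
    orders: np.ndarray
    site_arity: tuple[int, ...] = field(default=())

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def is_square(self) -> bool:
        return self.matrix.shape[0] == self.matrix.shape[1]

    def column_names(self) -> list[str]:
        """Human-readable term names: 1-based site numbers, ``s.b`` for
        tetrahedral bits (e.g. ``"1.2,4"``)."""
        names = []
        for label in self.labels:
            if not label:
                names.append("0")
                continue
            parts = []
            for site, bit in label:
                arity = self.site_arity[site] if self.site_arity else 2
                parts.append(f"{site + 1}" if arity == 2 else f"{site + 1}.{bit + 1}")
            names.append(",".join(parts))
        return names


def _site_bit_columns(site: Site, genotype_states: np.ndarray) -> np.ndarray:
    """(G, n_bits) ±1 bit columns for one site given its per-genotype states."""
    if site.n_states == 2:
        codes = {site.wildtype_state: (-1,)}
        codes[site.mutant_states[0]] = (1,)
    elif site.n_states == 4:
        codes = {site.wildtype_state: (1, 1, 1)}
        for s, corner in zip(site.mutant_states, _TETRAHEDRON):
            codes[s] = corner
    else:
        raise MapError(
            f"site {site.index}: {site.n_states}-state sites are unsupported "
            "(only 2- or 4-state)"
        )
    return np.array([codes[s] for s in genotype_states], dtype=np.int64)


def _encode(gpm: GenotypePhenotypeMap, max_order: int | str) -> EncodedGenotypes:
    L = gpm.n_sites
    if max_order == "full":
        max_order = L
    if not 1 <= int(max_order) <= L:
        raise ValueError(f"max_order must be in [1, {L}] or 'full'")
    max_order = int(max_order)

    genotypes = gpm.genotypes
    per_site = []
    for site in gpm.sites:
        states = np.array([g[site.index] for g in genotypes])
        per_site.append(_site_bit_columns(site, states))

    G = len(genotypes)
    columns = [np.ones(G, dtype=np.int64)]
    labels: list[tuple[tuple[int, int], ...]] = [()]
    orders = [0]
    for k in range(1, max_order + 1):
        for subset in itertools.combinations(range(L), k):
            bit_ranges = [range(per_site[s].shape[1]) for s in subset]
            for bits in itertools.product(*bit_ranges):
                col = np.ones(G, dtype=np.int64)
                for s, b in zip(subset, bits):
                    col = col * per_site[s][:, b]
                columns.append(col)
                labels.append(tuple(zip(subset, bits)))
                orders.append(k)
    return EncodedGenotypes(
        matrix=np.column_stack(columns),
        labels=tuple(labels),
        orders=np.asarray(orders, dtype=int),
        site_arity=tuple(s.n_states for s in gpm.sites),
    )


def walsh_encode(gpm: GenotypePhenotypeMap, max_order: int | str = "full") -> EncodedGenotypes:
    """±1 Walsh (Hadamard) design for an all-binary map.

    Wild type is coded −1 and mutant +1 at every site; interaction columns
    are products of per-site codes over site subsets of size <= ``max_order``.
    For the full order the matrix X is a 2^L × 2^L Hadamard matrix
    (XᵀX = 2^L·I), so coefficients are exact averages over the map.
    """
    for site in gpm.sites:
        if site.n_states != 2:
            raise MapError(
                f"site {site.index} has {site.n_states} states; walsh_encode "
                "requires binary sites — use wyk_encode for 4-state sites"
            )
    return _encode(gpm, max_order)


def wyk_encode(gpm: GenotypePhenotypeMap, max_order: int | str = "full") -> EncodedGenotypes:
    """WYK tetrahedral design for maps mixing binary and four-state sites.

    Each four-state site contributes three ±1 bit-columns: the wild type is
    coded (1, 1, 1) and the remaining states occupy tetrahedron corners
    (1,−1,−1), (−1,1,−1), (−1,−1,1) in state-list order. Binary sites
    contribute the single-column Walsh code, so an all-binary map encodes
    identically to :func:`walsh_encode`. Interaction columns are products of
    one bit-column from each site of a subset.
    """
    return _encode(gpm, max_order)


# ---------------------------------------------------------------------------
# File I/O
#
# JSON dialect: {"sites": [[state, ...], ...], "wildtype": str,
#                "data": [{"genotype", "phenotype", "stdev", "n"}, ...]}
# CSV/TSV: header genotype,phenotype,stdev,n; "." decimal separator; the
# wild type is all-"0" for 0/1 maps, otherwise the first data row.
# ---------------------------------------------------------------------------

_FLOAT_RE_OK = frozenset("0123456789.eE+-naifNAIF")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".csv", ".tsv", ".txt"):
        return "csv"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def _parse_number(text: str, what: str) -> float:
    text = text.strip()
    if not text or not set(text) <= _FLOAT_RE_OK:
        raise MapError(f"cannot parse {what} value {text!r} (use '.' decimals)")
    try:
        return float(text)
    except ValueError as exc:
        raise MapError(f"cannot parse {what} value {text!r}") from exc


def read_map(path: str | Path, format: str | None = None) -> GenotypePhenotypeMap:
    """Read and validate a genotype-phenotype map from JSON or CSV/TSV."""
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text(encoding="utf-8")
    if fmt == "json":
        return _map_from_json(text)
    if fmt == "csv":
        return _map_from_csv(text)
    raise ValueError(f"unknown format {fmt!r}")


def _map_from_json(text: str) -> GenotypePhenotypeMap:
    doc = json.loads(text)
    for key in ("sites", "wildtype", "data"):
        if key not in doc:
            raise MapError(f"JSON map missing top-level {key!r}")
    wildtype = doc["wildtype"]
    sites = [
        Site(index=i, states=tuple(states), wildtype_state=wildtype[i])
        for i, states in enumerate(doc["sites"])
    ]
    rows = []
    for rec in doc["data"]:
        for key in ("genotype", "phenotype", "stdev", "n"):
            if key not in rec:
                raise MapError(f"record {rec!r} missing field {key!r}")
        rows.append(
            (rec["genotype"], float(rec["phenotype"]), float(rec["stdev"]), int(rec["n"]))
        )
    records = pd.DataFrame(rows, columns=["genotype", "phenotype", "stdev", "n"])
    return GenotypePhenotypeMap(sites=sites, records=records)


def _map_from_csv(text: str) -> GenotypePhenotypeMap:
    sample = text[:4096]
    delimiter = "\t" if "\t" in sample.splitlines()[0] else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    required = {"genotype", "phenotype", "stdev", "n"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise MapError(
            f"CSV header must contain {sorted(required)}; got {reader.fieldnames}"
        )
    genotypes, phen, sd, n = [], [], [], []
    for row in reader:
        genotypes.append(row["genotype"].strip())
        phen.append(_parse_number(row["phenotype"], "phenotype"))
        sd.append(_parse_number(row["stdev"], "stdev"))
        n_val = _parse_number(row["n"], "n")
        if n_val != int(n_val):
            raise MapError(f"non-integer replicate count {row['n']!r}")
        n.append(int(n_val))
    if not genotypes:
        raise MapError("empty CSV map")
    L = len(genotypes[0])
    cols = [sorted({g[i] for g in genotypes}) for i in range(L)]
    if all(set(c) <= {"0", "1"} for c in cols):
        wildtype = "0" * L
    else:
        wildtype = genotypes[0]
    sites = [
        Site(index=i, states=tuple(cols[i]), wildtype_state=wildtype[i])
        for i in range(L)
    ]
    records = pd.DataFrame(
        {"genotype": genotypes, "phenotype": phen, "stdev": sd, "n": n}
    )
    return GenotypePhenotypeMap(sites=sites, records=records)


def write_map(
    gpm: GenotypePhenotypeMap, path: str | Path, format: str | None = None
) -> Path:
    """Write a map to disk; JSON round-trips bit-exactly through read_map."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        doc = {
            "sites": [list(s.states) for s in gpm.sites],
            "wildtype": gpm.wildtype,
            "data": [
                {
                    "genotype": row.genotype,
                    "phenotype": row.phenotype,
                    "stdev": row.stdev,
                    "n": int(row.n),
                }
                for row in gpm.records.itertuples()
            ],
        }
        path.write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")
    elif fmt == "csv":
        rec = gpm.records
        if not gpm.is_binary:
            # CSV readers take the first row as wild type for non-0/1 maps.
            wt = rec["genotype"] == gpm.wildtype
            rec = pd.concat([rec[wt], rec[~wt]])
        rec.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
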