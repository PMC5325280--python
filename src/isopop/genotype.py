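"""Diploid microsatellite genotype tables.

The universal currency of the pipeline is a table of individuals x loci with
two allele-size calls (in base pairs) per locus and a population label per
individual.  Supported on-disk dialects are the "wide" two-column-per-locus
layout (CSV/TSV/XLSX) and the classic GenePop format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 0  # allele slot value marking a missing call


class GenotypeParseError(ValueError):
    """Raised when an input file cannot be interpreted as a genotype table."""


class GenotypeValidationError(ValueError):
    """Raised when a parsed table violates a structural invariant."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus: a name and its repeat-unit (motif) length in bp."""

    name: str
    motif_length: int = 1

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise GenotypeValidationError(
                f"locus {self.name!r}: motif_length must be >= 1"
            )


@dataclass
class AlleleFrequencies:
    """Per-locus allele frequencies for one population.

    ``freqs[i]`` maps allele size (bp) to relative frequency among non-missing
    gene copies at locus ``i``; ``sample_genes[i]`` is the number of those gene
    copies.  Loci with zero genotyped copies carry an empty mapping and a zero
    count rather than raising.
    """

    loci: list[Locus]
    freqs: list[dict[int, float]]
    sample_genes: np.ndarray


class GenotypeTable:
    """In-memory diploid genotype matrix with population labels.

    Parameters
    ----------
    individuals
        Unique individual identifiers, length n.
    populations
        Population label per individual, length n.
    loci
        Locus descriptors, length L.
    calls
        Integer array of shape (n, L, 2) holding allele sizes in bp;
        0 encodes a missing call (both slots must then be 0).
    """

    def __init__(
        self,
        individuals: Sequence[str],
        populations: Sequence[str],
        loci: Sequence[Locus],
        calls: np.ndarray,
        validate: bool = True,
    ) -> None:
        self.individuals = list(individuals)
        self.populations = np.asarray(populations, dtype=object)
        self.loci = list(loci)
        self.calls = np.asarray(calls, dtype=np.int64)
        if validate:
            self.validate()

    # -- structure -----------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def validate(self) -> None:
        n, L = self.n_individuals, self.n_loci
        if self.calls.shape != (n, L, 2):
            raise GenotypeValidationError(
                f"calls shape {self.calls.shape} != ({n}, {L}, 2)"
            )
        if len(self.populations) != n:
            raise GenotypeValidationError("one population label per individual")
        if n and not all(self.populations):
            raise GenotypeValidationError("empty population label")
        if np.any(self.calls < 0):
            raise GenotypeValidationError("allele sizes must be positive (0=missing)")
        half = (self.calls == MISSING).sum(axis=2)
        if np.any(half == 1):
            i, j = np.argwhere(half == 1)[0]
            raise GenotypeValidationError(
                f"individual {self.individuals[i]!r}, locus "
                f"{self.loci[j].name!r}: one allele present, one missing"
            )
        for j, locus in enumerate(self.loci):
            sizes = self.calls[:, j, :]
            sizes = np.unique(sizes[sizes != MISSING])
            if sizes.size > 1 and np.any((sizes - sizes[0]) % locus.motif_length):
                raise GenotypeValidationError(
                    f"locus {locus.name!r}: allele sizes not congruent modulo "
                    f"motif length {locus.motif_length}"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and list(self.populations) == list(other.populations)
            and self.loci == other.loci
            and np.array_equal(np.sort(self.calls, 2), np.sort(other.calls, 2))
        )

    def subset(self, population: str) -> "GenotypeTable":
        """Rows belonging to one population."""
        mask = self.populations == population
        if not mask.any():
            raise KeyError(f"population {population!r} not in table")
        return GenotypeTable(
            [ind for ind, m in zip(self.individuals, mask) if m],
            self.populations[mask],
            self.loci,
            self.calls[mask],
            validate=False,
        )


def infer_motif_length(sizes: Iterable[int]) -> int:
    """GCD of pairwise allele-size differences; 1 for (near-)monomorphic loci."""
    arr = np.unique([s for s in sizes if s != MISSING])
    if arr.size < 2:
        return 1
    g = 0
    for d in np.diff(arr):
        g = math.gcd(g, int(d))
    return max(int(g), 1)


def allele_frequencies(table: GenotypeTable, population: str) -> AlleleFrequencies:
    """Allele frequencies over non-missing gene copies for one population."""
    sub = table.subset(population)
    freqs: list[dict[int, float]] = []
    genes = np.zeros(sub.n_loci, dtype=np.int64)
    for j in range(sub.n_loci):
        flat = sub.calls[:, j, :].ravel()
        flat = flat[flat != MISSING]
        genes[j] = flat.size
        if flat.size == 0:
            freqs.append({})
            continue
        vals, counts = np.unique(flat, return_counts=True)
        freqs.append({int(v): c / flat.size for v, c in zip(vals, counts)})
    return AlleleFrequencies(loci=list(sub.loci), freqs=freqs, sample_genes=genes)


# -- wide two-column-per-locus dialect ---------------------------------------


def _read_frame(path: Path) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix in {".xlsx", ".xls"}:
        return pd.read_excel(path, dtype=object)
    sep = "\t" if suffix in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, dtype=object)


def _parse_allele(token: object) -> int:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return MISSING
    s = str(token).strip()
    if s in {"", "0", "NA", "na", "-"}:
        return MISSING
    try:
        v = int(float(s))
    except ValueError as exc:
        raise GenotypeParseError(f"cannot parse allele size {token!r}") from exc
    if v < 0:
        raise GenotypeParseError(f"negative allele size {token!r}")
    return v


def read_wide(
    path: str | Path,
    id_column: str | int = 0,
    population_column: str | int = 1,
    population_mapping: Mapping[str, str] | None = None,
    motif_lengths: Mapping[str, int] | None = None,
) -> GenotypeTable:
    """Read the wide dialect: one row per individual, two columns per locus.

    Locus columns are taken pairwise after the id and population columns; a
    pair is named after its first header (pandas-style ``.1`` suffixes on the
    second column of a pair are ignored).  ``population_mapping`` optionally
    collapses site labels into analysis populations.  Motif lengths default to
    the GCD of allele-size differences per locus.
    """
    path = Path(path)
    frame = _read_frame(path)
    cols = list(frame.columns)

    def _col(key: str | int) -> str:
        return cols[key] if isinstance(key, int) else key

    idc, popc = _col(id_column), _col(population_column)
    locus_cols = [c for c in cols if c not in (idc, popc)]
    if len(locus_cols) % 2:
        raise GenotypeParseError(
            f"{path.name}: odd number of allele columns ({len(locus_cols)})"
        )
    pairs = [(locus_cols[k], locus_cols[k + 1]) for k in range(0, len(locus_cols), 2)]
    names = [str(a).split(".")[0].strip() for a, _ in pairs]

    individuals = [str(v) for v in frame[idc]]
    populations = [str(v) for v in frame[popc]]
    if population_mapping:
        populations = [population_mapping.get(p, p) for p in populations]

    n, L = len(individuals), len(pairs)
    calls = np.zeros((n, L, 2), dtype=np.int64)
    for j, (a, b) in enumerate(pairs):
        for i in range(n):
            try:
                x, y = _parse_allele(frame[a].iat[i]), _parse_allele(frame[b].iat[i])
            except GenotypeParseError as exc:
                raise GenotypeParseError(
                    f"{path.name}, row {i + 2}, locus {names[j]!r}: {exc}"
                ) from exc
            if (x == MISSING) != (y == MISSING):
                raise GenotypeParseError(
                    f"{path.name}, row {i + 2}, locus {names[j]!r}: "
                    "individual has one allele at a locus"
                )
            calls[i, j] = (x, y)

    loci = []
    for j, name in enumerate(names):
        m = (motif_lengths or {}).get(name) or infer_motif_length(calls[:, j, :].ravel())
        loci.append(Locus(name, m))
    return GenotypeTable(individuals, populations, loci, calls)


def write_wide(table: GenotypeTable, path: str | Path) -> None:
    """Write the wide dialect (CSV/TSV chosen by extension; missing = 0)."""
    path = Path(path)
    data: dict[str, list] = {
        "id": table.individuals,
        "population": list(table.populations),
    }
    for j, locus in enumerate(table.loci):
        data[locus.name] = table.calls[:, j, 0].tolist()
        data[f"{locus.name}.1"] = table.calls[:, j, 1].tolist()
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


# -- GenePop dialect ----------------------------------------------------------


def write_genepop(table: GenotypeTable, path: str | Path, title: str = "isopop export") -> None:
    """Write a GenePop file with one POP block per population label.

    Alleles are coded as 3-digit sizes; missing calls as ``000000``.
    """
    if table.calls.max(initial=0) > 999:
        raise GenotypeParseError(
            "GenePop 3-digit coding cannot represent allele sizes > 999"
        )
    lines = [title]
    lines.extend(locus.name for locus in table.loci)
    for pop in table.population_labels:
        lines.append("POP")
        sub = table.subset(pop)
        for i, ind in enumerate(sub.individuals):
            toks = [f"{sub.calls[i, j, 0]:03d}{sub.calls[i, j, 1]:03d}"
                    for j in range(sub.n_loci)]
            lines.append(f"{ind} ,  " + " ".join(toks))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(
    path: str | Path,
    population_names: Sequence[str] | None = None,
    motif_lengths: Mapping[str, int] | None = None,
) -> GenotypeTable:
    """Read a GenePop file (2- or 3-digit coding, comma-separated locus header
    or one locus per line).  POP blocks are labelled ``population_names`` if
    given, else ``pop1``, ``pop2``, ...
    """
    path = Path(path)
    raw = [ln.rstrip() for ln in path.read_text().splitlines()]
    if not raw:
        raise GenotypeParseError(f"{path.name}: empty file")
    body = raw[1:]
    locus_names: list[str] = []
    k = 0
    while k < len(body) and body[k].strip().upper() != "POP":
        part = body[k].strip()
        if part:
            locus_names.extend(s.strip() for s in part.split(","))
        k += 1
    if not locus_names or k == len(body):
        raise GenotypeParseError(f"{path.name}: no locus list / POP block found")

    individuals: list[str] = []
    populations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_index = -1
    for ln in body[k:]:
        stripped = ln.strip()
        if not stripped:
            continue
        if stripped.upper() == "POP":
            pop_index += 1
            continue
        if "," not in stripped:
            raise GenotypeParseError(f"{path.name}: malformed row {stripped!r}")
        name, _, rest = stripped.partition(",")
        toks = rest.split()
        if len(toks) != len(locus_names):
            raise GenotypeParseError(
                f"{path.name}, individual {name.strip()!r}: "
                f"{len(toks)} genotypes for {len(locus_names)} loci"
            )
        row = []
        for tok in toks:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenotypeParseError(
                    f"{path.name}, individual {name.strip()!r}: bad token {tok!r}"
                )
            half = len(tok) // 2
            row.append((int(tok[:half]), int(tok[half:])))
        individuals.append(name.strip())
        if population_names is not None:
            populations.append(population_names[pop_index])
        else:
            populations.append(f"pop{pop_index + 1}")
        rows.append(row)

    n, L = len(rows), len(locus_names)
    calls = np.zeros((n, L, 2), dtype=np.int64)
    for i, row in enumerate(rows):
        for j, (x, y) in enumerate(row):
            if (x == MISSING) != (y == MISSING):
                raise GenotypeParseError(
                    f"{path.name}, individual {individuals[i]!r}, locus "
                    f"{locus_names[j]!r}: individual has one allele at a locus"
                )
            calls[i, j] = (x, y)
    loci = []
    for j, name in enumerate(locus_names):
        m = (motif_lengths or {}).get(name) or infer_motif_length(calls[:, j, :].ravel())
        loci.append(Locus(name, m))
    return GenotypeTable(individuals, populations, loci, calls)


def read_genotype_table(
    path: str | Path,
    dialect: str = "wide_two_column",
    **kwargs,
) -> GenotypeTable:
    """Dispatch to the named dialect reader (``wide_two_column`` or ``genepop``)."""
    if dialect == "wide_two_column":
        return read_wide(path, **kwargs)
    if dialect == "genepop":
        return read_genepop(path, **kwargs)
    raise ValueError(f"unknown dialect {dialect!r}")
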