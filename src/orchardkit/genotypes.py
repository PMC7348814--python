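"""Codominant microsatellite genotype tables and allele frequencies.

A :class:`GenotypeTable` holds diploid allele-size calls for a set of
individuals typed at a panel of SSR loci, each individual carrying one
population (group) label — here the origin site of the clone.  Missing
genotypes are represented by an explicit boolean mask, never by a sentinel
allele code; the GenAlEx missing code ``0`` and the STRUCTURE missing code
``-9`` exist only at the file boundary.

Alleles are kept as raw fragment sizes internally.  Recoding to consecutive
integers happens only on STRUCTURE export, and the code map is persisted next
to the exported file so the recoding is invertible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GenotypeTable",
    "AlleleFrequencies",
    "GenotypeFormatError",
    "read_genalex",
    "write_genalex",
    "read_structure",
    "write_structure",
    "allele_frequencies",
]


class GenotypeFormatError(ValueError):
    """Raised when a genotype file violates its declared layout."""


@dataclass
class GenotypeTable:
    """Individuals x loci codominant allele-size calls with group labels.

    Parameters
    ----------
    individuals
        Ordered unique individual identifiers.
    loci
        Ordered unique locus names.
    populations
        Group label per individual (parallel to ``individuals``).
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)`` of allele codes
        (fragment sizes).  Entries under ``missing`` are ignored.
    missing
        Boolean array of shape ``(n_individuals, n_loci)``; ``True`` marks a
        missing (untyped) genotype.
    """

    individuals: list[str]
    loci: list[str]
    populations: list[str]
    calls: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=int)
        n, m = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, m, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {m}, 2); "
                "only diploid codominant data are supported"
            )
        if self.missing is None:
            self.missing = np.zeros((n, m), dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != (n, m):
            raise ValueError("missing mask shape mismatch")
        if len(self.populations) != n:
            raise ValueError("one population label per individual required")
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate individual IDs")
        if len(set(self.loci)) != m:
            raise ValueError("duplicate locus names")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def groups(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def call(self, individual: str, locus: str) -> tuple[int, int] | None:
        """Unordered allele pair for one genotype, or ``None`` if missing."""
        i = self.individuals.index(individual)
        l = self.loci.index(locus)
        if self.missing[i, l]:
            return None
        a, b = sorted(self.calls[i, l])
        return (int(a), int(b))

    def alleles_at(self, locus: str) -> list[int]:
        """Sorted distinct allele codes observed at a locus (all groups)."""
        l = self.loci.index(locus)
        ok = ~self.missing[:, l]
        return sorted(np.unique(self.calls[ok, l, :]).tolist()) if ok.any() else []

    def subset(self, individuals: list[str]) -> "GenotypeTable":
        idx = [self.individuals.index(i) for i in individuals]
        return GenotypeTable(
            individuals=[self.individuals[i] for i in idx],
            loci=list(self.loci),
            populations=[self.populations[i] for i in idx],
            calls=self.calls[idx].copy(),
            missing=self.missing[idx].copy(),
        )


@dataclass
class AlleleFrequencies:
    """Per-group and pooled relative allele frequencies.

    ``freqs[(group, locus)]`` maps allele code to relative frequency among the
    non-missing gene copies of that group at that locus; ``n_copies`` holds the
    (even) number of gene copies behind each entry.  ``pooled[locus]`` is the
    gene-copy-weighted pooled frequency (``tpi``) over all groups.
    """

    groups: list[str]
    loci: list[str]
    freqs: dict[tuple[str, str], dict[int, float]]
    n_copies: dict[tuple[str, str], int]
    pooled: dict[str, dict[int, float]]

    def p(self, group: str, locus: str) -> dict[int, float]:
        key = (group, locus)
        if key not in self.freqs:
            raise KeyError(f"no data for group {group!r} at locus {locus!r}")
        return self.freqs[key]


def allele_frequencies(table: GenotypeTable, grouping: str = "population") -> AlleleFrequencies:
    """Relative allele frequencies per (group, locus) plus pooled ``tpi``.

    ``grouping="population"`` groups by the table's population labels;
    ``grouping="pooled"`` treats the whole table as a single group ``"all"``.
    Missing genotypes are excluded from the gene-copy denominator.  A
    (group, locus) whose calls are all missing is simply absent from the
    result (flagged absent, never recorded as zero frequencies).
    """
    if grouping not in ("population", "pooled"):
        raise ValueError("grouping must be 'population' or 'pooled'")
    labels = table.populations if grouping == "population" else ["all"] * table.n_individuals
    order: dict[str, None] = {}
    for p in labels:
        order.setdefault(p)
    groups = list(order)

    freqs: dict[tuple[str, str], dict[int, float]] = {}
    n_copies: dict[tuple[str, str], int] = {}
    pooled: dict[str, dict[int, float]] = {}
    lab = np.asarray(labels)
    for l, locus in enumerate(table.loci):
        tot_counts: dict[int, int] = {}
        for g in groups:
            rows = (lab == g) & ~table.missing[:, l]
            if not rows.any():
                continue
            copies = table.calls[rows, l, :].ravel()
            counts: dict[int, int] = {}
            for a in copies.tolist():
                counts[a] = counts.get(a, 0) + 1
                tot_counts[a] = tot_counts.get(a, 0) + 1
            n = int(copies.size)
            freqs[(g, locus)] = {a: c / n for a, c in sorted(counts.items())}
            n_copies[(g, locus)] = n
        if tot_counts:
            n_tot = sum(tot_counts.values())
            pooled[locus] = {a: c / n_tot for a, c in sorted(tot_counts.items())}
    return AlleleFrequencies(groups=groups, loci=list(table.loci), freqs=freqs,
                             n_copies=n_copies, pooled=pooled)


# ---------------------------------------------------------------------------
# GenAlEx codominant CSV dialect
# ---------------------------------------------------------------------------

def read_genalex(path: str | Path) -> GenotypeTable:
    """Read a GenAlEx-style codominant CSV.

    Layout: row 1 = ``n_loci, n_samples, n_pops, size_1, ..., size_npops``;
    row 2 = title/population names (ignored); row 3 = header with locus names
    in every odd data column; then one row per sample:
    ``sample, pop, allele1, allele2, allele1, allele2, ...``.
    Allele code ``0`` means missing.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip(", \t")]
    if len(lines) < 4:
        raise GenotypeFormatError("file too short for GenAlEx layout")
    head = [c.strip() for c in lines[0].split(",")]
    try:
        n_loci, n_samples, n_pops = (int(head[i]) for i in range(3))
        pop_sizes = [int(c) for c in head[3:3 + n_pops]]
    except (ValueError, IndexError) as exc:
        raise GenotypeFormatError("malformed GenAlEx header row") from exc
    if sum(pop_sizes) != n_samples:
        raise GenotypeFormatError("population sizes do not sum to sample count")
    header = [c.strip() for c in lines[2].split(",")]
    loci = [header[2 + 2 * l] for l in range(n_loci)]
    if any(not name for name in loci):
        raise GenotypeFormatError("missing locus name in header row")

    rows = lines[3:]
    if len(rows) != n_samples:
        raise GenotypeFormatError(
            f"declared {n_samples} samples but found {len(rows)} data rows"
        )
    individuals: list[str] = []
    populations: list[str] = []
    calls = np.zeros((n_samples, n_loci, 2), dtype=int)
    missing = np.zeros((n_samples, n_loci), dtype=bool)
    for i, row in enumerate(rows):
        cells = [c.strip() for c in row.split(",")]
        if len(cells) < 2 + 2 * n_loci:
            raise GenotypeFormatError(f"row {i + 4}: expected {2 + 2 * n_loci} columns")
        extra = [c for c in cells[2 + 2 * n_loci:] if c]
        if extra:
            raise GenotypeFormatError(f"row {i + 4}: ragged row (extra columns)")
        individuals.append(cells[0])
        populations.append(cells[1])
        for l in range(n_loci):
            try:
                a = int(cells[2 + 2 * l])
                b = int(cells[3 + 2 * l])
            except ValueError as exc:
                raise GenotypeFormatError(f"row {i + 4}: non-integer allele") from exc
            if a == 0 or b == 0:
                if (a == 0) != (b == 0):
                    raise GenotypeFormatError(
                        f"row {i + 4}: half-missing genotype at locus {loci[l]}"
                    )
                missing[i, l] = True
            else:
                calls[i, l] = (a, b)
    if len(set(individuals)) != n_samples:
        raise GenotypeFormatError("duplicate individual ID")
    return GenotypeTable(individuals, loci, populations, calls, missing)


def write_genalex(table: GenotypeTable, path: str | Path, title: str = "orchardkit") -> None:
    """Write the GenAlEx codominant CSV dialect accepted by :func:`read_genalex`."""
    groups = table.groups
    sizes = [table.populations.count(g) for g in groups]
    # GenAlEx expects individuals contiguous by population
    order = [i for g in groups for i, p in enumerate(table.populations) if p == g]
    width = 2 + 2 * table.n_loci
    out: list[str] = []
    out.append(",".join([str(table.n_loci), str(table.n_individuals), str(len(groups))]
                        + [str(s) for s in sizes]))
    out.append(",".join([title, "", ""] + groups))
    hdr = ["Sample", "Pop"]
    for locus in table.loci:
        hdr += [locus, ""]
    out.append(",".join(hdr))
    for i in order:
        cells = [table.individuals[i], table.populations[i]]
        for l in range(table.n_loci):
            if table.missing[i, l]:
                cells += ["0", "0"]
            else:
                cells += [str(int(table.calls[i, l, 0])), str(int(table.calls[i, l, 1]))]
        assert len(cells) == width
        out.append(",".join(cells))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# STRUCTURE two-row format
# ---------------------------------------------------------------------------

def write_structure(table: GenotypeTable, path: str | Path) -> dict[str, dict[str, int]]:
    """Write STRUCTURE two-row-per-individual input; returns the code map.

    Alleles are recoded per locus to consecutive integers starting at 1 (sorted
    by fragment size); missing gene copies are written as ``-9``.  The code map
    ``{locus: {allele_size: code}}`` is also persisted as ``<path>.codemap.json``.
    """
    if table.n_individuals == 0 or table.n_loci == 0:
        raise ValueError("cannot export an empty table")
    codemap: dict[str, dict[str, int]] = {}
    lookup: list[dict[int, int]] = []
    for locus in table.loci:
        alleles = table.alleles_at(locus)
        m = {a: k + 1 for k, a in enumerate(alleles)}
        lookup.append(m)
        codemap[locus] = {str(a): c for a, c in m.items()}
    pops = {g: k + 1 for k, g in enumerate(table.groups)}
    out: list[str] = []
    for i, ind in enumerate(table.individuals):
        for copy in (0, 1):
            cells = [ind, str(pops[table.populations[i]])]
            for l in range(table.n_loci):
                if table.missing[i, l]:
                    cells.append("-9")
                else:
                    cells.append(str(lookup[l][int(table.calls[i, l, copy])]))
            out.append(" ".join(cells))
    p = Path(path)
    p.write_text("\n".join(out) + "\n")
    p.with_suffix(p.suffix + ".codemap.json").write_text(json.dumps(codemap, indent=1))
    return codemap


def read_structure(path: str | Path, loci: list[str] | None = None) -> GenotypeTable:
    """Read STRUCTURE two-row format (label, pop, one column per locus).

    Allele codes are taken at face value (no decoding); ``-9`` means missing.
    """
    rows = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(rows) % 2:
        raise GenotypeFormatError("odd number of rows: expected two per individual")
    n = len(rows) // 2
    n_loci = len(rows[0]) - 2
    if n_loci < 1:
        raise GenotypeFormatError("no locus columns found")
    if loci is None:
        loci = [f"L{l + 1}" for l in range(n_loci)]
    if len(loci) != n_loci:
        raise GenotypeFormatError("locus name count does not match columns")
    individuals, populations = [], []
    calls = np.zeros((n, n_loci, 2), dtype=int)
    missing = np.zeros((n, n_loci), dtype=bool)
    for i in range(n):
        r1, r2 = rows[2 * i], rows[2 * i + 1]
        if len(r1) != len(r2) or len(r1) != n_loci + 2:
            raise GenotypeFormatError(f"ragged rows for individual index {i}")
        if r1[0] != r2[0]:
            raise GenotypeFormatError(f"row pair label mismatch: {r1[0]} vs {r2[0]}")
        individuals.append(r1[0])
        populations.append(r1[1])
        for l in range(n_loci):
            a, b = int(r1[2 + l]), int(r2[2 + l])
            if a == -9 or b == -9:
                if (a == -9) != (b == -9):
                    raise GenotypeFormatError("half-missing genotype")
                missing[i, l] = True
            else:
                calls[i, l] = (a, b)
    if len(set(individuals)) != n:
        raise GenotypeFormatError("duplicate individual ID")
    return GenotypeTable(individuals, loci, populations, calls, missing)
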