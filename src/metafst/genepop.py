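"""GenePop-format genotype tables.

GenePop is the classic plain-text interchange format for codominant
genotypes: a title line, one locus name per line (or comma-separated),
then population blocks introduced by a line reading ``Pop``.  Each
individual line is ``<label> ,  <genotype> <genotype> ...`` where a
genotype is a fixed-width concatenation of two allele codes (2 or 3
digits each, i.e. 4- or 6-digit genotypes) and the all-zero code means
missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class GenePopError(ValueError):
    """Malformed GenePop input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class GenotypeTable:
    """Diploid multi-locus genotypes for individuals grouped in populations.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` and holds integer
    allele labels, with ``0`` marking a missing call (both gene copies of a
    call are missing together, as in GenePop).
    """

    individual_ids: list
    population_of: list
    loci: list
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individual_ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls must have shape ({n}, {L}, 2)")
        if len(self.population_of) != n:
            raise ValueError("one population assignment per individual required")
        half_missing = (self.calls == 0).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("calls must be diploid: both alleles present or both missing")

    @property
    def populations(self) -> list:
        seen: dict = {}
        for p in self.population_of:
            seen.setdefault(p, None)
        return list(seen)

    def population_sizes(self) -> dict:
        out: dict = {}
        for p in self.population_of:
            out[p] = out.get(p, 0) + 1
        return out

    def subset_populations(self, keep) -> "GenotypeTable":
        keep = set(keep)
        idx = [i for i, p in enumerate(self.population_of) if p in keep]
        return GenotypeTable(
            [self.individual_ids[i] for i in idx],
            [self.population_of[i] for i in idx],
            list(self.loci),
            self.calls[idx],
        )


def _parse_genotype(tok: str, line_no: int) -> tuple[int, int]:
    if len(tok) == 4:
        w = 2
    elif len(tok) == 6:
        w = 3
    else:
        raise GenePopError(f"genotype {tok!r} is neither 4 nor 6 digits", line_no)
    if not tok.isdigit():
        raise GenePopError(f"genotype {tok!r} contains non-digits", line_no)
    a, b = int(tok[:w]), int(tok[w:])
    if (a == 0) != (b == 0):
        raise GenePopError(f"half-missing genotype {tok!r}", line_no)
    return a, b


def read_genepop(path) -> GenotypeTable:
    """Read a GenePop file (4- or 6-digit dialect).

    Following the format's convention, each population is named by the
    label of the last individual in its block (duplicated names get a
    numeric suffix); individual ids are ``<population>_<ordinal>``.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenePopError("empty file", 1)
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        for name in lines[i].replace(",", "\n").splitlines():
            name = name.strip()
            if name:
                loci.append(name)
        i += 1
    if i == len(lines):
        raise GenePopError("no 'Pop' line found", len(lines))
    if not loci:
        raise GenePopError("no locus names before first 'Pop'", i + 1)

    blocks: list[list[tuple[str, list[tuple[int, int]]]]] = []
    for line_no0 in range(i, len(lines)):
        raw = lines[line_no0]
        line_no = line_no0 + 1
        if not raw.strip():
            continue
        if raw.strip().lower() == "pop":
            blocks.append([])
            continue
        if "," not in raw:
            raise GenePopError("individual line lacks a comma", line_no)
        label, geno = raw.split(",", 1)
        toks = geno.split()
        if len(toks) != len(loci):
            raise GenePopError(
                f"expected {len(loci)} genotypes, found {len(toks)}", line_no
            )
        blocks[-1].append(
            (label.strip(), [_parse_genotype(t, line_no) for t in toks])
        )
    blocks = [b for b in blocks if b]
    if not blocks:
        raise GenePopError("no individuals found", len(lines))

    ids: list[str] = []
    pops: list[str] = []
    calls: list[list[tuple[int, int]]] = []
    seen: dict[str, int] = {}
    for k, block in enumerate(blocks):
        name = block[-1][0] or f"pop_{k + 1}"
        seen[name] = seen.get(name, 0) + 1
        if seen[name] > 1:
            name = f"{name}_{seen[name]}"
        for j, (_, row) in enumerate(block):
            ids.append(f"{name}_{j + 1}")
            pops.append(name)
            calls.append(row)
    return GenotypeTable(ids, pops, loci, np.array(calls))


def write_genepop(table: GenotypeTable, path, title: str = "metafst export") -> None:
    """Write a GenotypeTable in the GenePop dialect its allele labels fit.

    Labels up to 99 are written 2 digits wide (4-digit genotypes); larger
    labels use 3 digits (6-digit genotypes).  Each individual line carries
    its population id as the label, so population identity survives a
    round trip.
    """
    width = 3 if int(table.calls.max(initial=0)) > 99 else 2
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for loc in table.loci:
            fh.write(str(loc) + "\n")
        current = None
        for pop, row in zip(table.population_of, table.calls):
            if pop != current:
                fh.write("Pop\n")
                current = pop
            genos = " ".join(f"{a:0{width}d}{b:0{width}d}" for a, b in row)
            fh.write(f"{pop} , {genos}\n")


def tally_counts(table: GenotypeTable) -> "AlleleCounts":
    """Count gene copies per population, locus and allele.

    Missing calls contribute nothing; per population and locus the counts
    sum to twice the number of non-missing individuals.
    """
    from .diversity import AlleleCounts

    pops = table.populations
    L = len(table.loci)
    alleles_per_locus = []
    for li in range(L):
        labs = np.unique(table.calls[:, li, :])
        alleles_per_locus.append([int(a) for a in labs if a != 0])
    A = max((len(a) for a in alleles_per_locus), default=0)
    counts = np.zeros((len(pops), L, max(A, 1)), dtype=np.int64)
    pop_index = {p: j for j, p in enumerate(pops)}
    for li in range(L):
        amap = {a: k for k, a in enumerate(alleles_per_locus[li])}
        for i in range(len(table.individual_ids)):
            j = pop_index[table.population_of[i]]
            a, b = table.calls[i, li]
            if a == 0:
                continue
            counts[j, li, amap[a]] += 1
            counts[j, li, amap[b]] += 1
    return AlleleCounts(pops, list(table.loci), alleles_per_locus, counts)
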