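"""PLINK text PED/MAP reading and writing, plus delimited result tables.

Conventions
-----------
* MAP: four whitespace-separated columns ``chrom vid cM bp``.  The genetic
  (cM) column is read and ignored; all distances downstream are in base pairs.
* PED: six leading columns (family, individual, father, mother, sex,
  phenotype) followed by two allele-code columns per locus.  Allele code
  ``"0"`` means missing; a genotype with any missing allele is MISSING.
* Allele orientation: at each locus the first allele code observed while
  scanning samples top-to-bottom (left allele first within a genotype) becomes
  alleleA; the other observed code becomes alleleB, whose copies the dosage
  counts.  A locus with a single observed code is monomorphic (all dosage 0)
  and gets the placeholder ``"0"`` as alleleB.
* Population labels come from a separate two-column TSV (sample, population)
  rather than the PED family-ID column.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import FormatError, NonBiallelicError
from .panel import MISSING, GenotypePanel, VariantRecord

MISSING_ALLELE = "0"


# --------------------------------------------------------------------- reading
def read_population_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample -> population TSV (no header)."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        out[parts[0]] = parts[1]
    return out


def _read_map(map_path: str | Path) -> list[tuple[str, str, int]]:
    records = []
    for lineno, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"{map_path}:{lineno}: MAP needs 4 columns, got {len(parts)}")
        chrom, vid, _cm, bp = parts
        try:
            pos = int(bp)
        except ValueError as exc:
            raise FormatError(f"{map_path}:{lineno}: bad bp position {bp!r}") from exc
        records.append((chrom, vid, pos))
    return records


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    pop_assignments: Mapping[str, str] | str | Path | None = None,
) -> GenotypePanel:
    """Read a PED/MAP pair into a :class:`GenotypePanel`.

    Parameters
    ----------
    pop_assignments
        Either a sample -> population mapping, a path to a two-column TSV, or
        None (every sample labelled ``"all"``).

    Raises
    ------
    FormatError
        PED row length inconsistent with the MAP locus count.
    NonBiallelicError
        More than two distinct non-missing allele codes at a locus.
    """
    map_records = _read_map(map_path)
    n_loci = len(map_records)

    sample_ids: list[str] = []
    rows: list[list[str]] = []
    for lineno, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_loci:
            raise FormatError(
                f"{ped_path}:{lineno}: expected {6 + 2 * n_loci} columns "
                f"for {n_loci} MAP loci, got {len(parts)}"
            )
        sample_ids.append(parts[1])
        rows.append(parts[6:])

    n_samples = len(rows)
    dosages = np.full((n_samples, n_loci), MISSING, dtype=np.int8)
    variants: list[VariantRecord] = []
    for j, (chrom, vid, pos) in enumerate(map_records):
        a_first: str | None = None
        a_second: str | None = None
        col = np.full(n_samples, MISSING, dtype=np.int8)
        pairs = [(rows[i][2 * j], rows[i][2 * j + 1]) for i in range(n_samples)]
        for i, (a1, a2) in enumerate(pairs):
            if a1 == MISSING_ALLELE or a2 == MISSING_ALLELE:
                continue
            for a in (a1, a2):
                if a_first is None:
                    a_first = a
                elif a_second is None and a != a_first:
                    a_second = a
                elif a not in (a_first, a_second):
                    raise NonBiallelicError(vid, {a_first, a_second, a})
            col[i] = (a1 != a_first) + (a2 != a_first)
        variants.append(
            VariantRecord(
                chrom=chrom, pos=pos, vid=vid,
                alleleA=a_first if a_first is not None else "A",
                alleleB=a_second if a_second is not None else MISSING_ALLELE,
            )
        )
        dosages[:, j] = col

    if pop_assignments is None:
        pop_of = {s: "all" for s in sample_ids}
    elif isinstance(pop_assignments, (str, Path)):
        pop_of = read_population_map(pop_assignments)
    else:
        pop_of = dict(pop_assignments)
    return GenotypePanel(dosages, sample_ids, pop_of, variants)


# --------------------------------------------------------------------- writing
def write_ped_map(panel: GenotypePanel, ped_path: str | Path, map_path: str | Path) -> None:
    """Write *panel* as a PED/MAP pair readable by :func:`read_ped_map`.

    Heterozygotes are written alleleA-first, so a panel in canonical
    orientation (see :meth:`GenotypePanel.canonicalize_orientation`) round
    trips to a bit-identical dosage matrix.
    """
    with open(map_path, "w") as fh:
        for v in panel.variants:
            fh.write(f"{v.chrom}\t{v.vid}\t0\t{v.pos}\n")

    with open(ped_path, "w") as fh:
        for i, sid in enumerate(panel.sample_ids):
            fields = [panel.population_of[sid], sid, "0", "0", "0", "-9"]
            for j, v in enumerate(panel.variants):
                d = int(panel.dosages[i, j])
                if d == MISSING:
                    fields += [MISSING_ALLELE, MISSING_ALLELE]
                elif d == 0:
                    fields += [v.alleleA, v.alleleA]
                elif d == 1:
                    fields += [v.alleleA, v.alleleB]
                else:
                    fields += [v.alleleB, v.alleleB]
            fh.write("\t".join(fields) + "\n")


def write_population_map(panel: GenotypePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in panel.sample_ids:
            fh.write(f"{s}\t{panel.population_of[s]}\n")


def format_value(x) -> str:
    """Table cell formatting: floats at 6 significant digits, NA for missing."""
    if x is None:
        return "NA"
    if isinstance(x, float):
        if math.isnan(x):
            return "NA"
        return f"{x:.6g}"
    return str(x)


def write_table(
    rows: Iterable[Sequence | Mapping],
    path: str | Path,
    columns: Sequence[str],
) -> None:
    """Write rows as a tab-separated table with a header.

    Rows may be sequences (ordered like *columns*) or mappings keyed by column
    name.  Floats are formatted at 6 significant digits; None/NaN become NA.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            if isinstance(row, Mapping):
                cells = [format_value(row.get(c)) for c in columns]
            else:
                if len(row) != len(columns):
                    raise FormatError(
                        f"row has {len(row)} cells for {len(columns)} columns"
                    )
                cells = [format_value(x) for x in row]
            fh.write("\t".join(cells) + "\n")
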