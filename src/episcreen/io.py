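"""Text-format I/O: PLINK .ped/.map, TSV dosage matrices, gene annotations.

Conventions
-----------
* Genotype codes count copies of the dataset-wide minor allele; ``0 0`` in a
  .ped file is a missing genotype, ``NA`` in a TSV matrix.
* Positions are 1-based (.map/VCF style) internally; BED annotation intervals
  are 0-based half-open, so a variant at 1-based position p falls in
  (start, end] i.e. start < p <= end.
* .ped leading columns: FID IID PAT MAT SEX PHENO with SEX 1=male 2=female
  0=unknown and PHENO 1=control 2=case.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .dataset import MISSING, GenotypeDataset, SampleInfo, VariantInfo

PathLike = Union[str, Path]

_SEX_TO_PED = {"unknown": "0", "male": "1", "female": "2"}
_PED_TO_SEX = {v: k for k, v in _SEX_TO_PED.items()}


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------


def read_plink_text(ped_path: PathLike, map_path: PathLike) -> GenotypeDataset:
    """Read a PLINK text fileset into a :class:`GenotypeDataset`.

    The minor allele of each variant is determined from the allele counts in
    the file (ties broken by taking the lexicographically smaller allele as
    ``allele_a``); genotypes are coded as minor-allele copies.  A site with
    more than two distinct alleles is a hard error naming the variant.
    """
    variants_meta = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{map_path}: line {ln}: expected 4 columns")
            chrom, vid, _cm, pos = parts[0], parts[1], parts[2], parts[3]
            variants_meta.append((vid, chrom, int(pos)))
    n_var = len(variants_meta)

    samples: list[SampleInfo] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_var:
                raise ValueError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * n_var} fields "
                    f"(6 + 2x{n_var} genotype alleles), got {len(parts)}"
                )
            _fid, iid, _pat, _mat, sex, pheno = parts[:6]
            status = {"1": "control", "2": "case"}.get(pheno)
            if status is None:
                raise ValueError(
                    f"{ped_path}: line {ln}: PHENO must be 1 (control) or 2 "
                    f"(case), got {pheno!r}"
                )
            samples.append(
                SampleInfo(
                    id=iid,
                    sex=_PED_TO_SEX.get(sex, "unknown"),
                    age=float("nan"),
                    status=status,
                )
            )
            allele_rows.append(
                [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_var)]
            )

    geno = np.full((len(samples), n_var), MISSING, dtype=np.int8)
    variants: list[VariantInfo] = []
    for j, (vid, chrom, pos) in enumerate(variants_meta):
        counts: dict[str, int] = {}
        for row in allele_rows:
            for a in row[j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        alleles = sorted(counts)
        if len(alleles) > 2:
            raise ValueError(
                f"variant {vid}: more than two alleles observed ({alleles})"
            )
        if len(alleles) == 0:
            minor, major = "A", "B"  # fully missing site: arbitrary labels
        elif len(alleles) == 1:
            minor, major = "0", alleles[0]  # monomorphic: minor unseen
        else:
            a, b = alleles  # lexicographic order
            if counts[a] < counts[b]:
                minor, major = a, b
            elif counts[b] < counts[a]:
                minor, major = b, a
            else:
                minor, major = a, b  # tie: lexicographically smaller is minor
        variants.append(
            VariantInfo(id=vid, chrom=chrom, pos=pos, allele_a=minor, allele_b=major)
        )
        for i, row in enumerate(allele_rows):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue  # '0 0' (or half-missing) -> missing
            geno[i, j] = (a1 == minor) + (a2 == minor)
    return GenotypeDataset(geno, variants, samples)


def write_plink_text(ds: GenotypeDataset, prefix: PathLike) -> tuple[Path, Path]:
    """Write ``<prefix>.ped`` and ``<prefix>.map``; returns the two paths."""
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for v in ds.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(ds.samples):
            pheno = "2" if s.status == "case" else "1"
            fields = [s.id, s.id, "0", "0", _SEX_TO_PED[s.sex], pheno]
            for j, v in enumerate(ds.variants):
                g = int(ds.genotypes[i, j])
                if g == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [
                        v.allele_a if g >= 1 else v.allele_b,
                        v.allele_a if g == 2 else v.allele_b,
                    ]
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# TSV dosage matrix (lossless 3-file round trip)
# ---------------------------------------------------------------------------


def write_tsv_matrix(ds: GenotypeDataset, prefix: PathLike) -> tuple[Path, Path, Path]:
    """Write ``<prefix>.matrix.tsv``, ``.samples.tsv`` and ``.variants.tsv``.

    The matrix is samples x variants with dosage codes and ``NA`` for
    missing; the sidecar tables carry the metadata needed for a lossless
    round trip.
    """
    prefix = Path(prefix)
    mpath = Path(f"{prefix}.matrix.tsv")
    spath = Path(f"{prefix}.samples.tsv")
    vpath = Path(f"{prefix}.variants.tsv")
    with open(mpath, "w") as fh:
        fh.write("sample_id\t" + "\t".join(ds.variant_ids) + "\n")
        for i, s in enumerate(ds.samples):
            row = [
                "NA" if g == MISSING else str(int(g)) for g in ds.genotypes[i]
            ]
            fh.write(s.id + "\t" + "\t".join(row) + "\n")
    write_sample_table(ds.samples, spath)
    with open(vpath, "w") as fh:
        fh.write("variant_id\tchrom\tpos\tallele_a\tallele_b\tgene\n")
        for v in ds.variants:
            fh.write(
                f"{v.id}\t{v.chrom}\t{v.pos}\t{v.allele_a}\t{v.allele_b}\t"
                f"{v.gene if v.gene is not None else 'NA'}\n"
            )
    return mpath, spath, vpath


def read_tsv_matrix(
    matrix_path: PathLike,
    samples_path: Optional[PathLike] = None,
    variants_path: Optional[PathLike] = None,
) -> GenotypeDataset:
    """Read a TSV dosage matrix; sidecar tables are optional.

    Without sidecars, sample status defaults to control and variant
    metadata is synthesised (chrom "1", positions by column order).
    Cells must be 0/1/2 or ``NA``.
    """
    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 1:
            raise ValueError(f"{matrix_path}: empty header")
        vids = header[1:]
        sids: list[str] = []
        rows: list[list[int]] = []
        for ln, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{matrix_path}: line {ln}: expected {len(header)} columns, "
                    f"got {len(parts)}"
                )
            sids.append(parts[0])
            row = []
            for cell in parts[1:]:
                if cell == "NA":
                    row.append(MISSING)
                elif cell in ("0", "1", "2"):
                    row.append(int(cell))
                else:
                    raise ValueError(
                        f"{matrix_path}: line {ln}: invalid dosage {cell!r}"
                    )
            rows.append(row)
    geno = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(vids)), dtype=np.int8)
    )

    if samples_path is not None:
        sample_map = {s.id: s for s in read_sample_table(samples_path)}
        samples = [sample_map[sid] for sid in sids]
    else:
        samples = [SampleInfo(id=sid) for sid in sids]

    if variants_path is not None:
        vmap = {}
        with open(variants_path) as fh:
            fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                vid, chrom, pos, aa, ab, gene = line.rstrip("\n").split("\t")
                vmap[vid] = VariantInfo(
                    id=vid,
                    chrom=chrom,
                    pos=int(pos),
                    allele_a=aa,
                    allele_b=ab,
                    gene=None if gene == "NA" else gene,
                )
        variants = [vmap[vid] for vid in vids]
    else:
        variants = [
            VariantInfo(id=vid, chrom="1", pos=j + 1) for j, vid in enumerate(vids)
        ]
    return GenotypeDataset(geno, variants, samples)


# ---------------------------------------------------------------------------
# Sample table
# ---------------------------------------------------------------------------


def write_sample_table(samples: list[SampleInfo], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsex\tage\tstatus\n")
        for s in samples:
            age = "NA" if math.isnan(s.age) else f"{s.age:g}"
            fh.write(f"{s.id}\t{s.sex}\t{age}\t{s.status}\n")


def read_sample_table(path: PathLike) -> list[SampleInfo]:
    samples = []
    with open(path) as fh:
        fh.readline()
        for ln, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: line {ln}: expected 4 columns")
            sid, sex, age, status = parts
            samples.append(
                SampleInfo(
                    id=sid,
                    sex=sex,
                    age=float("nan") if age == "NA" else float(age),
                    status=status,
                )
            )
    return samples


# ---------------------------------------------------------------------------
# Gene annotation (TSV or BED)
# ---------------------------------------------------------------------------


def read_gene_annotation(
    path: PathLike, variants: Optional[list[VariantInfo]] = None
) -> dict[str, str]:
    """Map variant ids to gene labels from a TSV or BED annotation file.

    A 2-column file ``snp_id<TAB>gene`` maps ids directly.  A 4-column BED
    file (``chrom start end gene``, 0-based half-open) requires ``variants``
    and labels each variant whose 1-based position p satisfies
    start < p <= end on the matching chromosome.  Later rows win on overlap.
    """
    tsv_rows: list[tuple[str, str]] = []
    bed_rows: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                tsv_rows.append((parts[0], parts[1]))
            elif len(parts) == 4:
                try:
                    bed_rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
                except ValueError:
                    raise ValueError(
                        f"{path}: line {ln}: malformed BED coordinates"
                    ) from None
            else:
                raise ValueError(
                    f"{path}: line {ln}: expected 2 (TSV) or 4 (BED) columns, "
                    f"got {len(parts)}"
                )
    if tsv_rows and bed_rows:
        raise ValueError(f"{path}: mixed TSV and BED rows")
    if bed_rows:
        if variants is None:
            raise ValueError("BED annotation requires variant metadata")
        mapping: dict[str, str] = {}
        for v in variants:
            for chrom, start, end, gene in bed_rows:
                if v.chrom == chrom and start < v.pos <= end:
                    mapping[v.id] = gene
        return mapping
    return dict(tsv_rows)
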