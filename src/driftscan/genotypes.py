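"""Genotype container and PLINK-dialect I/O.

One in-memory model serves the whole pipeline: a samples x variants
dosage matrix of small integers plus two metadata tables.  Dosage counts
copies of ``allele_a`` (the A1 column of the .bim dialect); 0 and 2 are
the two homozygotes, 1 the heterozygote, and :data:`MISSING` (-1) an
out-of-band sentinel for a missing call.

Coordinates follow the 1-based inclusive convention of .bim/.map files
throughout the package; conversion to 0-based half-open happens only at
the BED boundary in the annotation module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Out-of-band sentinel for a missing diploid call (0 is a valid dosage).
MISSING: int = -1

#: Magic bytes opening a SNP-major PLINK .bed file.
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

#: PLINK 2-bit code -> dosage of A1 copies (01 = missing).
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

GROUP_CASE = "I"     # capped hock present
GROUP_CONTROL = "II"  # capped hock absent

_GROUP_ALIASES = {
    "I": GROUP_CASE, "1": GROUP_CASE, "case": GROUP_CASE,
    "II": GROUP_CONTROL, "2": GROUP_CONTROL, "control": GROUP_CONTROL,
}


class FormatError(ValueError):
    """A companion file is malformed or internally inconsistent."""


def _ext(prefix: Path, ext: str) -> Path:
    return prefix.parent / (prefix.name + ext)


def chrom_sort_key(chrom: str) -> tuple:
    """Sort key placing numeric chromosomes first, in numeric order."""
    s = str(chrom)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes with sample and variant metadata.

    Attributes
    ----------
    dosage
        ``(n_samples, n_variants)`` int8 array of A1-allele counts in
        {0, 1, 2} or :data:`MISSING`.
    samples
        DataFrame with columns ``sample_id``, ``breed``, ``group``
        (group is ``"I"``/``"II"`` or None before assignment).
    variants
        DataFrame with columns ``id``, ``chrom``, ``pos_bp``,
        ``allele_a``, ``allele_b``; sorted by (chrom, pos_bp).
    """

    dosage: np.ndarray
    samples: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x variants)")
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError(f"dosage contains {bad.sum()} values outside {{0,1,2,MISSING}}")
        if self.variants["id"].duplicated().any():
            dup = self.variants.loc[self.variants["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if (self.variants["pos_bp"] < 1).any():
            raise ValueError("variant positions must be >= 1 (1-based)")
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def missing_fraction(self) -> np.ndarray:
        """Per-variant fraction of missing calls."""
        return (self.dosage == MISSING).mean(axis=0)

    def sample_missing_fraction(self) -> np.ndarray:
        """Per-sample fraction of missing calls."""
        return (self.dosage == MISSING).mean(axis=1)

    def take_variants(self, index: np.ndarray | Iterable[int]) -> "GenotypeMatrix":
        idx = np.asarray(list(index) if not isinstance(index, np.ndarray) else index)
        return GenotypeMatrix(
            self.dosage[:, idx], self.samples.copy(), self.variants.iloc[idx].reset_index(drop=True)
        )

    def take_samples(self, index: np.ndarray | Iterable[int]) -> "GenotypeMatrix":
        idx = np.asarray(list(index) if not isinstance(index, np.ndarray) else index)
        return GenotypeMatrix(
            self.dosage[idx, :], self.samples.iloc[idx].reset_index(drop=True), self.variants.copy()
        )

    def sort_variants(self) -> "GenotypeMatrix":
        """Stable sort of variants by (chrom, pos_bp); samples untouched."""
        keys = [chrom_sort_key(c) for c in self.variants["chrom"]]
        order = np.array(
            pd.DataFrame({"k": keys, "p": self.variants["pos_bp"]})
            .sort_values(["k", "p"], kind="stable")
            .index
        )
        return self.take_variants(order)

    def drop_nonautosomal(self) -> "GenotypeMatrix":
        """Drop variants whose chromosome label is not purely numeric (X, Y, MT...)."""
        keep = np.array([str(c).isdigit() for c in self.variants["chrom"]])
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d non-autosomal variants", n_drop)
        return self.take_variants(np.flatnonzero(keep))

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            np.array_equal(self.dosage, other.dosage)
            and self.samples["sample_id"].tolist() == other.samples["sample_id"].tolist()
            and self.variants[["id", "chrom", "pos_bp", "allele_a", "allele_b"]]
            .reset_index(drop=True)
            .equals(
                other.variants[["id", "chrom", "pos_bp", "allele_a", "allele_b"]].reset_index(
                    drop=True
                )
            )
        )


def _phenotype_to_group(value: str) -> str | None:
    return {"2": GROUP_CASE, "1": GROUP_CONTROL}.get(value)


def _group_to_phenotype(group) -> str:
    return {GROUP_CASE: "2", GROUP_CONTROL: "1"}.get(group, "-9")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotypes(path_prefix: str | Path, dialect: str = "binary") -> GenotypeMatrix:
    """Read a PLINK fileset (``binary``: .bed/.bim/.fam, ``text``: .ped/.map).

    Variants are sorted by (chrom, pos_bp) after loading; sample order is
    preserved as on disk.  For the text dialect, which records no A1/A2
    designation, allele_a is canonicalized to the minor allele (ties and
    monomorphic sites: the lexicographically smaller observed allele).
    """
    prefix = Path(path_prefix)
    if dialect == "binary":
        g = _read_binary(prefix)
    elif dialect == "text":
        g = _read_text(prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return g.sort_variants()


def _read_fam(path: Path) -> pd.DataFrame:
    rows = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        f = line.split()
        if len(f) < 6:
            raise FormatError(f"{path}: expected 6 columns, got {len(f)}")
        rows.append(
            {"sample_id": f[1], "breed": None if f[0] == "0" else f[0],
             "group": _phenotype_to_group(f[5])}
        )
    return pd.DataFrame(rows, columns=["sample_id", "breed", "group"])


def _read_bim(path: Path) -> pd.DataFrame:
    rows = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        f = line.split()
        if len(f) != 6:
            raise FormatError(f"{path} line {i}: expected 6 columns, got {len(f)}")
        rows.append(
            {"id": f[1], "chrom": f[0], "pos_bp": int(f[3]), "allele_a": f[4], "allele_b": f[5]}
        )
    return pd.DataFrame(rows, columns=["id", "chrom", "pos_bp", "allele_a", "allele_b"])


def _read_binary(prefix: Path) -> GenotypeMatrix:
    bed, bim, fam = (_ext(prefix, s) for s in (".bed", ".bim", ".fam"))
    for p in (bed, bim, fam):
        if not p.exists():
            raise FileNotFoundError(p)
    samples = _read_fam(fam)
    variants = _read_bim(bim)
    n, m = len(samples), len(variants)
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise FormatError(f"{bed}: not a SNP-major PLINK .bed file (bad magic)")
    bpv = (n + 3) // 4  # bytes per variant
    body = raw[3:]
    if body.size != m * bpv:
        raise FormatError(
            f"{bed}: size implies {body.size // max(bpv, 1)} variants but {bim} lists {m}"
        )
    codes = body.reshape(m, bpv)
    # unpack 2-bit fields, sample index little-endian within each byte
    expanded = np.empty((m, bpv * 4), dtype=np.int8)
    for shift in range(4):
        expanded[:, shift::4] = _CODE_TO_DOSAGE[(codes >> (2 * shift)) & 0b11]
    dosage = expanded[:, :n].T.copy()
    return GenotypeMatrix(dosage, samples, variants)


def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        f = line.split()
        if len(f) != 4:
            raise FormatError(f"{path} line {i}: expected 4 columns, got {len(f)}")
        rows.append({"id": f[1], "chrom": f[0], "pos_bp": int(f[3])})
    return pd.DataFrame(rows, columns=["id", "chrom", "pos_bp"])


def _read_text(prefix: Path) -> GenotypeMatrix:
    ped, map_ = _ext(prefix, ".ped"), _ext(prefix, ".map")
    for p in (ped, map_):
        if not p.exists():
            raise FileNotFoundError(p)
    vmeta = _read_map(map_)
    m = len(vmeta)
    sample_rows = []
    allele_pairs: list[list[tuple[str, str]]] = []
    for i, line in enumerate(ped.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        f = line.split()
        if len(f) != 6 + 2 * m:
            raise FormatError(
                f"{ped} line {i}: expected {6 + 2 * m} fields for {m} variants "
                f"in {map_}, got {len(f)}"
            )
        sample_rows.append(
            {"sample_id": f[1], "breed": None if f[0] == "0" else f[0],
             "group": _phenotype_to_group(f[5])}
        )
        allele_pairs.append(list(zip(f[6::2], f[7::2])))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "breed", "group"])
    n = len(samples)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    a1 = np.empty(m, dtype=object)
    a2 = np.empty(m, dtype=object)
    for j in range(m):
        counts: dict[str, int] = {}
        for i in range(n):
            x, y = allele_pairs[i][j]
            for al in (x, y):
                if al != "0":
                    counts[al] = counts.get(al, 0) + 1
        if len(counts) > 2:
            raise FormatError(
                f"{ped}: variant {vmeta['id'][j]!r} has >2 alleles {sorted(counts)}"
            )
        # minor allele as allele_a; ties / monomorphic: lexicographic
        ordered = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if not ordered:
            a1[j], a2[j] = "0", "0"
        elif len(ordered) == 1:
            a1[j], a2[j] = ordered[0][0], "0"
        else:
            a1[j], a2[j] = ordered[0][0], ordered[1][0]
        for i in range(n):
            x, y = allele_pairs[i][j]
            if x == "0" or y == "0":
                if x != y:
                    raise FormatError(
                        f"{ped} line {i + 1}: half-missing genotype {x} {y} "
                        f"at variant {vmeta['id'][j]!r}"
                    )
                continue  # stays MISSING
            d = 0
            for al in (x, y):
                if al == a1[j]:
                    d += 1
                elif al != a2[j]:
                    raise FormatError(
                        f"{ped} line {i + 1}: unknown genotype symbol {al!r} "
                        f"at variant {vmeta['id'][j]!r}"
                    )
            dosage[i, j] = d
    variants = vmeta.assign(allele_a=a1, allele_b=a2)[
        ["id", "chrom", "pos_bp", "allele_a", "allele_b"]
    ]
    return GenotypeMatrix(dosage, samples, variants)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_genotypes(g: GenotypeMatrix, path_prefix: str | Path, dialect: str = "binary") -> list[Path]:
    """Write ``g`` as a PLINK fileset; lossless partner of :func:`read_genotypes`."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "binary":
        return _write_binary(g, prefix)
    if dialect == "text":
        return _write_text(g, prefix)
    raise ValueError(f"unknown dialect {dialect!r}")


def _fam_lines(g: GenotypeMatrix) -> str:
    out = []
    for _, s in g.samples.iterrows():
        fid = s["breed"] if s["breed"] else "0"
        out.append(f"{fid} {s['sample_id']} 0 0 0 {_group_to_phenotype(s['group'])}")
    return "\n".join(out) + "\n"


def _write_binary(g: GenotypeMatrix, prefix: Path) -> list[Path]:
    bed, bim, fam = (_ext(prefix, s) for s in (".bed", ".bim", ".fam"))
    fam.write_text(_fam_lines(g))
    bim.write_text(
        "".join(
            f"{v['chrom']}\t{v['id']}\t0\t{v['pos_bp']}\t{v['allele_a']}\t{v['allele_b']}\n"
            for _, v in g.variants.iterrows()
        )
    )
    n, m = g.n_samples, g.n_variants
    bpv = (n + 3) // 4
    code = np.empty((m, bpv * 4), dtype=np.uint8)
    code[:] = 0b01  # pad slots read back as missing but are never consumed
    dos = g.dosage.T  # variant-major
    lut = np.zeros(256, dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        lut[d & 0xFF] = c
    code[:, :n] = lut[dos.view(np.uint8)]
    packed = np.zeros((m, bpv), dtype=np.uint8)
    for shift in range(4):
        packed |= code[:, shift::4] << (2 * shift)
    with open(bed, "wb") as fh:
        fh.write(_BED_MAGIC)
        packed.tofile(fh)
    return [bed, bim, fam]


def _write_text(g: GenotypeMatrix, prefix: Path) -> list[Path]:
    ped, map_ = _ext(prefix, ".ped"), _ext(prefix, ".map")
    map_.write_text(
        "".join(f"{v['chrom']}\t{v['id']}\t0\t{v['pos_bp']}\n" for _, v in g.variants.iterrows())
    )
    a1 = g.variants["allele_a"].to_numpy()
    a2 = g.variants["allele_b"].to_numpy()
    lines = []
    for i in range(g.n_samples):
        s = g.samples.iloc[i]
        fid = s["breed"] if s["breed"] else "0"
        fields = [str(fid), str(s["sample_id"]), "0", "0", "0", _group_to_phenotype(s["group"])]
        for j in range(g.n_variants):
            d = g.dosage[i, j]
            if d == MISSING:
                fields += ["0", "0"]
            elif d == 2:
                fields += [a1[j], a1[j]]
            elif d == 1:
                fields += [a1[j], a2[j]]
            else:
                if a2[j] == "0":
                    raise ValueError(
                        f"variant {g.variants['id'][j]!r}: dosage 0 with no recorded allele_b"
                    )
                fields += [a2[j], a2[j]]
        lines.append(" ".join(fields))
    ped.write_text("\n".join(lines) + ("\n" if lines else ""))
    return [ped, map_]


# ---------------------------------------------------------------------------
# group assignment
# ---------------------------------------------------------------------------

def attach_groups(
    g: GenotypeMatrix, assignments: Mapping[str, str] | pd.DataFrame | str | Path
) -> GenotypeMatrix:
    """Attach case/control group labels; drop samples without an assignment.

    ``assignments`` maps sample_id -> group (``I``/``II``, or ``1``/``2``,
    ``case``/``control``); a DataFrame with those two columns or a path to
    a 2-column TSV is also accepted.  Assignment ids absent from ``g`` are
    reported as a warning, not an error; conflicting duplicate assignments
    are fatal.
    """
    if isinstance(assignments, (str, Path)):
        df = pd.read_csv(assignments, sep="\t", header=None, comment="#", dtype=str)
        if list(df.iloc[0]) == ["sample_id", "group"]:
            df = df.iloc[1:]
        pairs = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    elif isinstance(assignments, pd.DataFrame):
        pairs = list(zip(assignments["sample_id"].astype(str), assignments["group"].astype(str)))
    else:
        pairs = [(str(k), str(v)) for k, v in assignments.items()]

    mapping: dict[str, str] = {}
    for sid, grp in pairs:
        norm = _GROUP_ALIASES.get(grp.strip())
        if norm is None:
            raise ValueError(f"unknown group label {grp!r} for sample {sid!r}")
        if sid in mapping and mapping[sid] != norm:
            raise ValueError(f"conflicting group assignments for sample {sid!r}")
        mapping[sid] = norm

    known = set(g.samples["sample_id"])
    unknown = sorted(set(mapping) - known)
    if unknown:
        logger.warning("%d assignment ids not present in genotypes: %s", len(unknown), unknown)
    keep = [i for i, sid in enumerate(g.samples["sample_id"]) if sid in mapping]
    n_drop = g.n_samples - len(keep)
    if n_drop:
        logger.info("dropping %d samples without a group assignment", n_drop)
    out = g.take_samples(keep)
    out.samples = out.samples.assign(
        group=[mapping[sid] for sid in out.samples["sample_id"]]
    )
    return out
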