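"""On-disk formats for panels, phenotypes and shared summaries.

Everything exchanged between data holders is plain text except the
precision matrix, whose m(m+1)/2 lower triangle is stored packed as 8-byte
little-endian floats behind a 16-byte header (8-byte magic ``MGSLHSB1`` +
m as an unsigned 8-byte integer).  A summary on disk is three files sharing
one stem:

* ``<stem>.tsv``     — snp_id, allele_freq and (optionally) effect, rhs
* ``<stem>.meta``    — key=value scalars (dgv_var, err_var, n_pheno, ...)
* ``<stem>.lhsbin``  — the packed lower triangle (bit-exact round-trip)

Dosage tables are tab-separated with a header row of SNP ids (encoded
``chrom:name``) and the individual id in the first column — a PLINK
".raw"-like dialect without the family columns.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FileFormatError
from .types import GenotypePanel, PhenotypeRecords, PopulationSummary, SimScenario

__all__ = [
    "read_dosage", "write_dosage", "read_phenotypes", "write_phenotypes",
    "read_summary", "write_summary", "read_lhs_triangle", "write_lhs_triangle",
    "read_corr", "write_corr", "write_effects", "read_scenario",
    "pack_lower_triangle", "unpack_lower_triangle",
]

_MAGIC = b"MGSLHSB1"
_HEADER = struct.Struct("<8sQ")


def _split_snp_id(s: str) -> tuple[str, str]:
    if ":" in s:
        c, _, _ = s.partition(":")
        return c, s
    return "1", s


def write_dosage(panel: GenotypePanel, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("indiv_id\t" + "\t".join(map(str, panel.snp_ids)) + "\n")
        for ind, row in zip(panel.indiv_ids, panel.dosage):
            fh.write(str(ind) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_dosage(path) -> GenotypePanel:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "indiv_id":
        raise FileFormatError("dosage table must start with an 'indiv_id' column",
                              path=path, line=1)
    snp_ids = np.array(df.columns[1:], dtype=object)
    try:
        dosage = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as e:
        raise FileFormatError(f"non-numeric dosage entry ({e})", path=path) from None
    if not np.isfinite(dosage).all():
        raise FileFormatError("non-finite dosage entry", path=path)
    chrom = np.array([_split_snp_id(s)[0] for s in snp_ids], dtype=object)
    return GenotypePanel(snp_ids, chrom, dosage.astype(np.int8),
                         df["indiv_id"].to_numpy(dtype=object))


def write_phenotypes(records: PhenotypeRecords, path) -> None:
    ids = records.indiv_ids
    if ids is None:
        ids = np.array([f"i{k}" for k in range(len(records))], dtype=object)
    pd.DataFrame({"indiv_id": ids, "y": records.y,
                  "n_daughters": records.n_daughters}).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_phenotypes(path) -> PhenotypeRecords:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("indiv_id", "y", "n_daughters"):
        if col not in df.columns:
            raise FileFormatError(f"phenotype table lacks column {col!r}",
                                  path=path, line=1)
    if not np.isfinite(df["y"]).all() or not np.isfinite(df["n_daughters"]).all():
        raise FileFormatError("non-finite phenotype value", path=path)
    return PhenotypeRecords(y=df["y"].to_numpy(float),
                            n_daughters=df["n_daughters"].to_numpy(float),
                            indiv_ids=df["indiv_id"].to_numpy(object))


def pack_lower_triangle(mat: np.ndarray) -> np.ndarray:
    """Row-major packed lower triangle (including the diagonal)."""
    mat = np.asarray(mat, dtype=float)
    return mat[np.tril_indices(mat.shape[0])]


def unpack_lower_triangle(packed: np.ndarray, m: int) -> np.ndarray:
    out = np.zeros((m, m))
    out[np.tril_indices(m)] = packed
    out = out + np.tril(out, -1).T
    return out


def write_lhs_triangle(mat: np.ndarray, path) -> None:
    """Binary packed lower triangle; bit-exact round-trip guaranteed."""
    mat = np.asarray(mat, dtype=float)
    m = mat.shape[0]
    packed = pack_lower_triangle(mat).astype("<f8")
    with Path(path).open("wb") as fh:
        fh.write(_HEADER.pack(_MAGIC, m))
        fh.write(packed.tobytes())


def read_lhs_triangle(path) -> np.ndarray:
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER.size:
        raise FileFormatError("file shorter than the 16-byte header",
                              path=path, offset=len(raw))
    magic, m = _HEADER.unpack_from(raw)
    if magic != _MAGIC:
        raise FileFormatError(
            f"bad magic {magic!r}, expected {_MAGIC!r}", path=path, offset=0)
    expected = _HEADER.size + 8 * m * (m + 1) // 2
    if len(raw) != expected:
        raise FileFormatError(
            f"expected {expected} bytes for m={m}, found {len(raw)}",
            path=path, offset=min(len(raw), expected))
    packed = np.frombuffer(raw, dtype="<f8", offset=_HEADER.size)
    if not np.isfinite(packed).all():
        bad = int(np.flatnonzero(~np.isfinite(packed))[0])
        raise FileFormatError("non-finite matrix entry", path=path,
                              offset=_HEADER.size + 8 * bad)
    return unpack_lower_triangle(packed, m)


def write_summary(summary: PopulationSummary, stem) -> None:
    """Write the three summary files sharing the path stem."""
    stem = Path(stem)
    cols = {"snp_id": summary.snp_ids, "allele_freq": summary.allele_freq}
    if summary.effects is not None:
        cols["effect"] = summary.effects
    if summary.rhs is not None:
        cols["rhs"] = summary.rhs
    pd.DataFrame(cols).to_csv(stem.with_suffix(".tsv"), sep="\t",
                              index=False, float_format="%.10g")
    meta = {"dgv_var": summary.dgv_var, "err_var": summary.err_var,
            "n_pheno": summary.n_pheno, "n_geno": summary.n_geno,
            "population": summary.population, "trait": summary.trait}
    with stem.with_suffix(".meta").open("w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}={v}\n")
    write_lhs_triangle(summary.lhs, stem.with_suffix(".lhsbin"))


def read_summary(stem) -> PopulationSummary:
    stem = Path(stem)
    tsv = stem.with_suffix(".tsv")
    df = pd.read_csv(tsv, sep="\t")
    for col in ("snp_id", "allele_freq"):
        if col not in df.columns:
            raise FileFormatError(f"summary table lacks column {col!r}",
                                  path=tsv, line=1)
    meta_path = stem.with_suffix(".meta")
    meta: dict[str, str] = {}
    for ln, line in enumerate(meta_path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FileFormatError("expected key=value", path=meta_path, line=ln)
        k, _, v = line.partition("=")
        meta[k.strip()] = v.strip()
    try:
        dgv_var = float(meta["dgv_var"])
        err_var = float(meta["err_var"])
        n_pheno = int(meta["n_pheno"])
        n_geno = int(meta["n_geno"])
    except KeyError as e:
        raise FileFormatError(f"metadata lacks key {e.args[0]!r}",
                              path=meta_path) from None
    lhs = read_lhs_triangle(stem.with_suffix(".lhsbin"))
    if lhs.shape[0] != len(df):
        raise FileFormatError(
            f"lhs is {lhs.shape[0]}x{lhs.shape[0]} but the summary table has "
            f"{len(df)} SNPs", path=stem.with_suffix(".lhsbin"))
    return PopulationSummary(
        snp_ids=df["snp_id"].to_numpy(object),
        allele_freq=df["allele_freq"].to_numpy(float), lhs=lhs,
        rhs=df["rhs"].to_numpy(float) if "rhs" in df.columns else None,
        effects=df["effect"].to_numpy(float) if "effect" in df.columns else None,
        dgv_var=dgv_var, err_var=err_var, n_pheno=n_pheno, n_geno=n_geno,
        population=meta.get("population", "pop"),
        trait=meta.get("trait", "trait"))


def write_corr(corr: np.ndarray, pop_ids, path) -> None:
    pd.DataFrame(np.asarray(corr, float), index=list(pop_ids),
                 columns=list(pop_ids)).to_csv(path, sep="\t",
                                               float_format="%.10g")


def read_corr(path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FileFormatError("correlation row and column ids differ",
                              path=path)
    return df.to_numpy(dtype=float), list(df.columns)


def write_effects(snp_ids, effects_by_pop: dict[str, np.ndarray], path) -> None:
    cols = {"snp_id": np.asarray(snp_ids, dtype=object)}
    cols.update({k: np.asarray(v, float) for k, v in effects_by_pop.items()})
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False,
                              float_format="%.10g")


def read_scenario(path) -> SimScenario:
    """Read a simulation scenario from a YAML key/value config."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"scenario config not found: {path}")
    with path.open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("scenario config must be a key/value mapping")
    known = set(SimScenario.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown scenario keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigError("scenario config must set an explicit seed")
    try:
        return SimScenario(**raw)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid scenario config: {e}") from None
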