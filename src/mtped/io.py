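"""File formats: pedigree tables, relatedness matrices, fit results.

Two pedigree dialects are supported:

* ``fam`` — PLINK-compatible whitespace columns FID IID PAT MAT SEX PHENO,
  with 0 for a missing parent, SEX 1 = male / 2 = female, and -9 for a
  missing phenotype.  Generations are inferred from the parent links.
* ``csv`` — extended CSV with header
  ``fid,id,father,mother,sex,generation,married_in[,phenotype]``,
  empty fields for missing values and sex coded F/M.

Relatedness matrices export to Matrix Market coordinate format (symmetric
real) or dense CSV with an identifier header; fit results and bias
summaries round-trip through versioned JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .bias import BiasSummary
from .model import VarianceComponentResults
from .pedigree import FEMALE, MALE, PedigreeError, PedigreeTable
from .phenotypes import VarianceComponents
from .relatedness import ComponentMatrices

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "write_matrices",
    "read_matrix",
    "write_fit_result",
    "read_fit_result",
    "write_bias_summary",
]

SCHEMA_VERSION = 1
_FAM_COLUMNS = ["fid", "iid", "pat", "mat", "sex", "pheno"]


def infer_generations(table: PedigreeTable) -> np.ndarray:
    """Infer generation labels for a table lacking them.

    Members with recorded parents sit one generation below the deeper
    parent; parentless members co-parenting with a placed member adopt
    their partner's generation; remaining founders default to 1.
    """
    n = table.n
    gen = np.zeros(n, dtype=np.int16)
    order = table.topological_order()
    for i in order:
        f, m = int(table.father[i]), int(table.mother[i])
        if f >= 0:
            gen[i] = max(gen[f], gen[m], 0) + 1 if gen[f] or gen[m] else 2
    # co-parents of placed members adopt the partner's generation
    for _ in range(n):
        changed = False
        for i in range(n):
            f, m = int(table.father[i]), int(table.mother[i])
            if f >= 0:
                g = max(int(gen[f]), int(gen[m]))
                if g:
                    for par in (f, m):
                        if gen[par] == 0:
                            gen[par] = g
                            changed = True
                    if gen[i] != g + 1:
                        gen[i] = g + 1
                        changed = True
        if not changed:
            break
    gen[gen == 0] = 1
    return gen


def _table_from_frame(df: pd.DataFrame, fid: str) -> PedigreeTable:
    ids = df["id"].to_numpy(dtype=np.int64)
    id_pos = {int(v): i for i, v in enumerate(ids)}
    n = len(ids)

    def parent_positions(col: str) -> np.ndarray:
        out = np.full(n, -1, dtype=np.int64)
        for i, raw in enumerate(df[col].tolist()):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or int(raw) == 0:
                continue
            pid = int(raw)
            if pid not in id_pos:
                raise PedigreeError(
                    f"pedigree {fid!r}: member {int(ids[i])} references missing "
                    f"{col} {pid}"
                )
            out[i] = id_pos[pid]
        return out

    father = parent_positions("father")
    mother = parent_positions("mother")
    table = PedigreeTable(
        member_id=ids,
        father=father,
        mother=mother,
        sex=df["__sex_code"].to_numpy(dtype=np.int8),
        generation=np.zeros(n, dtype=np.int16),
        married_in=df.get(
            "married_in", pd.Series(False, index=df.index)
        ).to_numpy(dtype=bool),
        pedigree_id=fid,
        phenotype=df["phenotype"].to_numpy(dtype=float)
        if "phenotype" in df and df["phenotype"].notna().any()
        else None,
    )
    if "generation" in df and df["generation"].notna().all():
        table.generation = df["generation"].to_numpy(dtype=np.int16)
    else:
        table.generation = infer_generations(table)
    table.validate()
    return table


def read_pedigree(path: str | Path, dialect: str | None = None) -> list[PedigreeTable]:
    """Read pedigrees from a fam or extended-CSV file, grouped by family id."""
    path = Path(path)
    if dialect is None:
        dialect = "fam" if path.suffix == ".fam" else "csv"
    if dialect == "fam":
        df = pd.read_csv(path, sep=r"\s+", header=None, names=_FAM_COLUMNS)
        bad = ~df["sex"].isin([1, 2])
        if bad.any():
            raise PedigreeError(
                f"malformed sex codes in {path}: {sorted(df['sex'][bad].unique())}"
            )
        frame = pd.DataFrame(
            {
                "fid": df["fid"].astype(str),
                "id": df["iid"],
                "father": df["pat"],
                "mother": df["mat"],
                "__sex_code": np.where(df["sex"] == 1, MALE, FEMALE),
                "phenotype": df["pheno"].where(df["pheno"] != -9, np.nan),
            }
        )
    elif dialect == "csv":
        df = pd.read_csv(path)
        sex = df["sex"].astype(str).str.upper()
        bad = ~sex.isin(["F", "M"])
        if bad.any():
            raise PedigreeError(
                f"malformed sex codes in {path}: {sorted(sex[bad].unique())}"
            )
        frame = df.rename(columns={"fid": "fid", "id": "id"}).copy()
        frame["fid"] = frame["fid"].astype(str)
        frame["__sex_code"] = np.where(sex == "M", MALE, FEMALE)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    tables = []
    for fid, group in frame.groupby("fid", sort=False):
        tables.append(_table_from_frame(group.reset_index(drop=True), str(fid)))
    return tables


def write_pedigree(
    peds: list[PedigreeTable], path: str | Path, dialect: str | None = None
) -> None:
    """Write pedigrees to disk in the fam or extended-CSV dialect."""
    path = Path(path)
    if dialect is None:
        dialect = "fam" if path.suffix == ".fam" else "csv"
    frames = [p.to_dataframe() for p in peds]
    df = pd.concat(frames, ignore_index=True)
    if dialect == "csv":
        df.to_csv(path, index=False)
        return
    if dialect != "fam":
        raise ValueError(f"unknown dialect {dialect!r}")
    pheno = df["phenotype"] if "phenotype" in df else pd.Series(np.nan, index=df.index)
    fam = pd.DataFrame(
        {
            "fid": df["fid"],
            "iid": df["id"],
            "pat": df["father"],
            "mat": df["mother"],
            "sex": np.where(df["sex"] == "M", 1, 2),
            "pheno": pheno.fillna(-9),
        }
    )
    fam.to_csv(path, sep=" ", header=False, index=False)


def write_matrices(
    mats: ComponentMatrices, out_dir: str | Path, fmt: str = "mtx"
) -> list[Path]:
    """Export one block's matrices, one file per component (A, I_AA, ...)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, mat in mats.as_dict().items():
        if fmt == "mtx":
            target = out_dir / f"{mats.pedigree_id}_{name}.mtx"
            mmwrite(str(target), sparse.coo_matrix(mat), symmetry="symmetric")
        elif fmt == "csv":
            target = out_dir / f"{mats.pedigree_id}_{name}.csv"
            pd.DataFrame(mat, index=mats.index, columns=mats.index).to_csv(target)
        else:
            raise ValueError(f"unknown matrix format {fmt!r}")
        written.append(target)
    return written


def read_matrix(path: str | Path) -> np.ndarray:
    """Read one exported matrix back to a dense array."""
    path = Path(path)
    if path.suffix == ".mtx":
        return np.asarray(mmread(str(path)).todense())
    return pd.read_csv(path, index_col=0).to_numpy(dtype=float)


def write_fit_result(result: VarianceComponentResults, path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "estimates": result.estimates.as_dict(),
        "free_components": list(result.spec.free),
        "neg2ll": result.neg2ll,
        "converged": result.converged,
        "n_function_evals": result.n_function_evals,
        "n_individuals": result.n_individuals,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_fit_result(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["estimates"] = VarianceComponents(**payload["estimates"])
    return payload


def write_bias_summary(summary: BiasSummary, path: str | Path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **summary.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
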