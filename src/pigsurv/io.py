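"""Plain-text readers/writers: PLINK-style maps and dosages, pedigree CSV.

These let the fitting side consume external data (pedigree + marker map +
dosage files) in place of the simulator's output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .popsim import MarkerMap

__all__ = [
    "write_map",
    "read_map",
    "write_raw",
    "read_raw",
    "write_pedigree",
    "read_pedigree",
    "write_phenotypes",
    "read_phenotypes",
]

PED_COLS = ["id", "sire", "dam", "sex", "generation", "litter", "alive"]


def write_relationship_sparse(rel, path, threshold: float = 0.0) -> None:
    """Relationship matrix as three-column text (id_i, id_j, value).

    Writes the lower triangle including the diagonal; entries with
    |value| <= threshold are dropped.
    """
    import numpy as _np

    vals = rel.values
    ids = rel.ids
    with open(path, "w") as fh:
        fh.write("id_i\tid_j\tvalue\n")
        for i in range(len(ids)):
            for j in range(i + 1):
                v = vals[i, j]
                if abs(v) > threshold or i == j:
                    fh.write(f"{ids[i]}\t{ids[j]}\t{_np.format_float_positional(v)}\n")


def read_relationship_sparse(path):
    """Read a three-column sparse matrix back into (dense values, ids)."""
    import numpy as _np

    df = pd.read_csv(path, sep="\t")
    ids = _np.unique(_np.concatenate([df["id_i"], df["id_j"]]))
    pos = {v: k for k, v in enumerate(ids)}
    n = len(ids)
    M = _np.zeros((n, n))
    for i, j, v in df.itertuples(index=False):
        M[pos[i], pos[j]] = v
        M[pos[j], pos[i]] = v
    return M, ids


def write_map(mmap: MarkerMap, path, loci: str = "markers") -> None:
    """PLINK .map-style text: chr, locus_id, cM, index (+ class column).

    ``loci`` selects "markers", "qtl" or "all"; the class column marks each
    row as marker or qtl.
    """
    sel = {
        "markers": mmap.marker_idx,
        "qtl": mmap.qtl_idx,
        "all": np.arange(mmap.n_loci),
    }[loci]
    df = pd.DataFrame(
        {
            "chr": mmap.chrom[sel],
            "locus_id": mmap.ids[sel],
            "cm": mmap.pos_cm[sel],
            "index": sel,
            "class": np.where(mmap.is_qtl[sel], "qtl", "marker"),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_raw(dosages: np.ndarray, ids: np.ndarray, locus_ids, path) -> None:
    """PLINK .raw-style dosage table: header of locus IDs, one row per id."""
    df = pd.DataFrame(np.asarray(dosages, dtype=int), columns=list(locus_ids))
    df.insert(0, "IID", ids)
    df.to_csv(path, sep=" ", index=False)


def read_raw(path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (ids, dosage matrix)."""
    df = pd.read_csv(path, sep=" ")
    ids = df["IID"].to_numpy()
    return ids, df.drop(columns="IID").to_numpy(dtype=float)


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    pedigree[PED_COLS].to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    return pd.read_csv(path)[PED_COLS]


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    """Phenotype CSV; the TBV columns are simulation truth retained for
    validation only and must not be used as data by any model."""
    cols = ["id", "generation", "litter", "y", "liability", "tbv_a", "tbv_m"]
    phenotypes[cols].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)
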