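"""Reading and writing the pipeline's tabular formats.

Counts travel as TSV (feature rows with a ``region`` column, sample-id
columns) or MatrixMarket plus row/column sidecar TSVs; manifests and
phenotypes as CSV.  A small reference table of published generation
night-sleep means for the selection experiment ships with the package.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_counts_tsv(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if "region" not in counts.columns:
        raise ValueError(f"{path}: counts TSV must have a 'region' column")
    return counts


def write_counts_mtx(counts: pd.DataFrame, prefix) -> None:
    """Write counts as <prefix>.mtx with .rows.tsv / .cols.tsv sidecars."""
    prefix = Path(prefix)
    mat, region = counts.drop(columns="region"), counts["region"]
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(mat.to_numpy()))
    pd.DataFrame({"feature_id": mat.index, "region": region.to_numpy()}).to_csv(
        prefix.with_suffix(".rows.tsv"), sep="\t", index=False
    )
    pd.DataFrame({"sample_id": mat.columns}).to_csv(
        prefix.with_suffix(".cols.tsv"), sep="\t", index=False
    )


def read_counts_mtx(prefix) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = np.asarray(spio.mmread(str(prefix.with_suffix(".mtx"))).todense())
    rows = pd.read_csv(prefix.with_suffix(".rows.tsv"), sep="\t")
    cols = pd.read_csv(prefix.with_suffix(".cols.tsv"), sep="\t")
    counts = pd.DataFrame(
        mat.astype(np.int64),
        index=pd.Index(rows["feature_id"], name="feature_id"),
        columns=cols["sample_id"],
    )
    counts.insert(0, "region", rows["region"].to_numpy())
    return counts


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_reference_sleep_means() -> pd.DataFrame:
    """Published night-sleep population means (minutes) at generations 0/13.

    Columns: scheme, replicate, generation, mean_night_sleep.
    """
    with resources.files("somnet.data").joinpath("night_sleep_generation_means.csv").open() as fh:
        return pd.read_csv(fh)
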