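"""Readers/writers for the canonical on-disk formats.

On disk, count tables follow the field convention taxa x samples (OTU ids in
the first column, sample ids in the header); in memory, modeling code uses
samples x OTUs.  Tables are tab-delimited UTF-8 without quoting; trees are
Newick with branch lengths; fit results are a TSV of coefficients plus a JSON
sidecar of scalar settings and diagnostics.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .phylo import PatristicDistanceMatrix
from .solver import SICSFit

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "read_distance_matrix",
    "write_matrix",
    "read_tree",
    "align_inputs",
    "write_fit",
    "read_fit",
    "write_manifest",
]

logger = logging.getLogger(__name__)


def read_count_table(path, metadata_samples=None) -> pd.DataFrame:
    """Read a taxa x samples count TSV.

    Validates integer, nonnegative entries and unique ids.  If
    ``metadata_samples`` is given and the header does not match it but the
    first column does, the table is auto-transposed with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"duplicate row or column ids in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"non-numeric cells in {path}: {err}") from err
    if np.any(values < 0):
        bad = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at row {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r}"
        )
    if np.any(values != np.round(values)):
        raise ValueError(f"non-integer counts in {path}")
    if metadata_samples is not None:
        meta = set(map(str, metadata_samples))
        cols = set(map(str, df.columns))
        rows = set(map(str, df.index))
        if not (cols & meta) and (rows & meta):
            logger.warning(
                "count table %s appears transposed (sample ids found in "
                "rows); auto-transposing", path,
            )
            df = df.T
    return df.astype(np.int64)


def write_count_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV: sample ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    return df


def read_distance_matrix(path) -> PatristicDistanceMatrix:
    """Square distance TSV with matching header row and index column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"distance matrix {path} row/column labels differ")
    return PatristicDistanceMatrix([str(x) for x in df.index],
                                   df.to_numpy(dtype=float))


def write_matrix(M: np.ndarray, labels, path) -> None:
    pd.DataFrame(M, index=labels, columns=labels).to_csv(path, sep="\t")


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def align_inputs(counts: pd.DataFrame, distances: PatristicDistanceMatrix,
                 metadata: pd.DataFrame):
    """Align OTU and sample orders across the three inputs.

    Counts are taxa x samples.  Any OTU present in the counts but absent
    from the distance matrix (or vice versa), or sample missing from the
    metadata, is a hard error listing the offenders.
    """
    otus = [str(o) for o in counts.index]
    missing = sorted(set(otus) - set(distances.labels))
    extra = sorted(set(distances.labels) - set(otus))
    if missing or extra:
        raise ValueError(
            f"OTU mismatch between counts and distances; in counts only: "
            f"{missing[:10]}; in distances only: {extra[:10]}"
        )
    if not otus:
        raise ValueError("empty OTU set")
    distances = distances.reorder(otus)
    samples = [str(s) for s in counts.columns]
    missing_s = sorted(set(samples) - set(map(str, metadata.index)))
    if missing_s:
        raise ValueError(f"samples missing from metadata: {missing_s}")
    metadata = metadata.loc[samples]
    return counts, distances, metadata


def write_fit(fit: SICSFit, otu_ids, outdir, extra: dict | None = None) -> None:
    """Serialize a fit: coefficients TSV + JSON sidecar of settings."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "otu": list(otu_ids),
        "beta_std": fit.beta_std,
        "beta_orig": fit.beta_orig,
        "center": fit.center,
        "scale": fit.scale,
    }).to_csv(outdir / "coefficients.tsv", sep="\t", index=False)
    sidecar = {
        "family": fit.family,
        "intercept": fit.intercept,
        "intercept_orig": fit.intercept_orig,
        "lambda1": fit.lambda1,
        "lambda2": fit.lambda2,
        "gamma": fit.gamma,
        "n_iter": fit.n_iter,
        "converged": fit.converged,
    }
    if extra:
        sidecar.update(extra)
    (outdir / "fit.json").write_text(json.dumps(_jsonable(sidecar), indent=2))


def read_fit(outdir) -> tuple[SICSFit, list[str]]:
    outdir = Path(outdir)
    coef = pd.read_csv(outdir / "coefficients.tsv", sep="\t")
    meta = json.loads((outdir / "fit.json").read_text())
    fit = SICSFit(
        family=meta["family"], intercept=meta["intercept"],
        beta_std=coef["beta_std"].to_numpy(),
        intercept_orig=meta["intercept_orig"],
        beta_orig=coef["beta_orig"].to_numpy(),
        n_iter=meta["n_iter"], converged=meta["converged"],
        objective_trace=np.array([]), center=coef["center"].to_numpy(),
        scale=coef["scale"].to_numpy(), lambda1=meta["lambda1"],
        lambda2=meta["lambda2"], gamma=meta["gamma"],
    )
    return fit, [str(o) for o in coef["otu"]]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_manifest(outdir, config: dict) -> None:
    """Write the fully resolved run configuration (with seeds) as JSON."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"package_version": __version__, **_jsonable(config)}
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=2))
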