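"""File formats: count matrices, annotations, and the reference bundle.

Counts are always genes x columns (cells or samples): Matrix Market
(.mtx with ``genes.tsv`` / ``barcodes.tsv`` sidecars in the same
directory) or dense TSV/CSV with gene ids in the first column and a
header row of column ids. The fitted reference is persisted as a
directory bundle of TSV tables plus ``metadata.json``; numeric tables
are written with 17 significant digits so load(save(panel)) reproduces
the panel bit-exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csc_matrix

from .errors import BundleError, ValidationError
from .reference import SCHEMA_VERSION, ReferencePanel
from .weights import CrossSampleWeights

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"

_BUNDLE_TABLES = (
    "genes.tsv",
    "cell_types.tsv",
    "mu.tsv",
    "var.tsv",
    "dispersion.tsv",
    "success_prob.tsv",
    "specificity_weights.tsv",
    "fit_flags.tsv",
)


def _check_counts(mat: np.ndarray, gene_ids: list[str], path) -> None:
    if np.any(mat < 0):
        raise ValidationError(f"{path}: negative entries in count matrix")
    seen: dict[str, int] = {}
    dups = []
    for g in gene_ids:
        seen[g] = seen.get(g, 0) + 1
        if seen[g] == 2:
            dups.append(g)
    if dups:
        raise ValidationError(f"{path}: duplicated gene ids: {dups[:10]}")


def load_counts(path, dialect: str | None = None) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a genes x columns count matrix; returns (matrix, gene_ids, col_ids)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    if dialect is None:
        dialect = {".mtx": "mtx", ".tsv": "tsv", ".csv": "csv"}.get(path.suffix.lower())
        if dialect is None:
            raise ValidationError(f"cannot infer dialect from extension of {path}")
    if dialect == "mtx":
        try:
            m = mmread(path)
        except Exception as exc:  # noqa: BLE001 - surface the parser's message
            raise ValidationError(f"{path}: malformed Matrix Market file: {exc}") from exc
        mat = np.asarray(m.todense() if hasattr(m, "todense") else m, dtype=float)
        genes_path = path.parent / "genes.tsv"
        cells_path = path.parent / "barcodes.tsv"
        for p in (genes_path, cells_path):
            if not p.exists():
                raise ValidationError(f"missing Matrix Market sidecar: {p}")
        gene_ids = genes_path.read_text().split()
        col_ids = cells_path.read_text().split()
        if mat.shape != (len(gene_ids), len(col_ids)):
            raise ValidationError(
                f"{path}: matrix shape {mat.shape} does not match sidecars "
                f"({len(gene_ids)} genes, {len(col_ids)} columns)"
            )
    elif dialect in ("tsv", "csv"):
        sep = "\t" if dialect == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise ValidationError(f"{path}: parse error: {exc}") from exc
        if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
            bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise ValidationError(f"{path}: non-numeric columns: {bad[:5]}")
        mat = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        col_ids = [str(c) for c in df.columns]
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    _check_counts(mat, gene_ids, path)
    return mat, gene_ids, col_ids


def save_counts(path, mat: np.ndarray, gene_ids: list[str], col_ids: list[str]) -> None:
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        mmwrite(str(path), csc_matrix(mat))
        (path.parent / "genes.tsv").write_text("\n".join(gene_ids) + "\n")
        (path.parent / "barcodes.tsv").write_text("\n".join(col_ids) + "\n")
    else:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        pd.DataFrame(mat, index=gene_ids, columns=col_ids).to_csv(
            path, sep=sep, float_format=_FLOAT_FMT
        )


def load_annotations(path, cell_ids: list[str]) -> tuple[np.ndarray, np.ndarray | None]:
    """TSV with columns cell_id, cell_type[, subject], aligned to ``cell_ids``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cell_id", "cell_type"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    extra = set(df.columns) - {"cell_id", "cell_type", "subject"}
    if extra:
        logger.info("%s: ignoring extra columns %s", path, sorted(extra))
    lut = df.set_index("cell_id")
    if lut.index.has_duplicates:
        dups = lut.index[lut.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicated cell ids: {dups[:10]}")
    missing = [c for c in cell_ids if c not in lut.index]
    if missing:
        raise ValidationError(
            f"{path}: {len(missing)} cells in counts lack annotations, e.g. {missing[:10]}"
        )
    cell_types = lut.loc[cell_ids, "cell_type"].to_numpy(dtype=object)
    subjects = None
    if "subject" in lut.columns and lut["subject"].notna().all():
        subjects = lut.loc[cell_ids, "subject"].to_numpy(dtype=object)
    return cell_types, subjects


def _write_matrix_tsv(path: Path, mat: np.ndarray, index: list[str], columns: list[str]) -> None:
    pd.DataFrame(mat, index=index, columns=columns).to_csv(
        path, sep="\t", float_format=_FLOAT_FMT
    )


def _read_matrix_tsv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise BundleError(f"reference bundle is missing {path.name}")
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def save_reference(panel: ReferencePanel, bundle_dir) -> None:
    """Write a :class:`ReferencePanel` as a versioned directory bundle."""
    d = Path(bundle_dir)
    d.mkdir(parents=True, exist_ok=True)
    meta = dict(panel.metadata)
    meta.setdefault("schema_version", SCHEMA_VERSION)
    meta["gene_mode"] = panel.gene_mode
    (d / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    (d / "genes.tsv").write_text("\n".join(panel.selected_genes) + "\n")
    (d / "cell_types.tsv").write_text("\n".join(panel.cell_types) + "\n")
    g, t = panel.selected_genes, panel.cell_types
    _write_matrix_tsv(d / "mu.tsv", panel.mu, g, t)
    _write_matrix_tsv(d / "var.tsv", panel.var, g, t)
    _write_matrix_tsv(d / "dispersion.tsv", panel.dispersion, g, t)
    _write_matrix_tsv(d / "success_prob.tsv", panel.success_prob, g, t)
    pd.DataFrame({"specificity_weight": panel.specificity_weight}, index=g).to_csv(
        d / "specificity_weights.tsv", sep="\t", float_format=_FLOAT_FMT
    )
    pd.DataFrame(panel.fit_flag, index=g, columns=t).to_csv(d / "fit_flags.tsv", sep="\t")


def load_reference(bundle_dir) -> ReferencePanel:
    d = Path(bundle_dir)
    meta_path = d / "metadata.json"
    if not meta_path.exists():
        raise BundleError(f"reference bundle is missing metadata.json ({d})")
    meta = json.loads(meta_path.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise BundleError(
            f"bundle schema_version {meta.get('schema_version')!r} is not supported "
            f"(expected {SCHEMA_VERSION!r}); no migration path"
        )
    for name in _BUNDLE_TABLES:
        if not (d / name).exists():
            raise BundleError(f"reference bundle is missing {name}")
    genes = (d / "genes.tsv").read_text().split()
    types = (d / "cell_types.tsv").read_text().split()
    mu = _read_matrix_tsv(d / "mu.tsv")
    panel = ReferencePanel(
        selected_genes=genes,
        cell_types=types,
        mu=mu.to_numpy(dtype=float),
        var=_read_matrix_tsv(d / "var.tsv").to_numpy(dtype=float),
        dispersion=_read_matrix_tsv(d / "dispersion.tsv").to_numpy(dtype=float),
        success_prob=_read_matrix_tsv(d / "success_prob.tsv").to_numpy(dtype=float),
        specificity_weight=_read_matrix_tsv(d / "specificity_weights.tsv")[
            "specificity_weight"
        ].to_numpy(dtype=float),
        fit_flag=_read_matrix_tsv(d / "fit_flags.tsv").to_numpy(dtype=object),
        gene_mode=meta.get("gene_mode", "markers"),
        metadata=meta,
    )
    panel.validate()
    return panel


def save_cross_sample_weights(weights: CrossSampleWeights, path) -> None:
    pd.DataFrame(
        {"gene_id": weights.gene_ids, "vmr": weights.vmr, "w_c": weights.w_c,
         "mode": weights.mode, "fit_flag": weights.fit_flag}
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def load_cross_sample_weights(path) -> CrossSampleWeights:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, float_precision="round_trip")
    return CrossSampleWeights(
        gene_ids=df["gene_id"].tolist(),
        vmr=df["vmr"].to_numpy(dtype=float),
        w_c=df["w_c"].to_numpy(dtype=float),
        mode=str(df["mode"].iloc[0]) if len(df) else "compound_replicates",
        fit_flag=df["fit_flag"].to_numpy(dtype=object),
    )


def save_proportions(result, path, decimals: int = 6) -> None:
    """Proportions TSV: sample_id, one column per cell type, converged, loss."""
    df = result.to_frame().copy()
    for c in result.cell_types:
        df[c] = df[c].round(decimals)
    df.to_csv(path, sep="\t")


def save_diagnostics(result, path) -> None:
    """Full-precision per-sample diagnostics as JSON."""
    out = {
        "cell_types": result.cell_types,
        "samples": {
            sid: {
                "theta": result.theta[i].tolist(),
                "beta_raw": result.beta_raw[i].tolist(),
                "tau_coarse": result.tau_coarse[i].tolist(),
                "lambda": float(result.lambda_used[i]),
                "loss": float(result.loss_value[i]),
                "n_iter": int(result.n_iter[i]),
                "converged": bool(result.converged[i]),
            }
            for i, sid in enumerate(result.sample_ids)
        },
    }
    Path(path).write_text(json.dumps(out, indent=2) + "\n")
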