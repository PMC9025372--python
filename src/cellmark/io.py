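"""Data model and on-disk formats for the marker-discovery pipeline.

The pipeline's universal input is a cells × genes non-negative expression
matrix plus a per-cell label vector (cell type).  Matrices are accepted as
MatrixMarket triplets (with ``genes.tsv`` / ``barcodes.tsv`` sidecars, in
either orientation) or as dense TSV; labels as a two-column TSV.  Outputs
(ranked feature lists, IFS curves, rule sets) are plain TSV/JSON and
round-trip losslessly through the matching readers in this module.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class DataFormatError(ValueError):
    """Raised when an input file violates the expected format or invariants."""


@dataclass
class ExpressionMatrix:
    """Cells × genes non-negative expression values with identifiers.

    ``values`` has shape ``(len(cell_ids), len(gene_ids))``; both identifier
    lists are unique and ordered.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise DataFormatError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise DataFormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells × {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise DataFormatError("duplicate gene_ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise DataFormatError("duplicate cell_ids")
        if self.values.size and np.min(self.values) < 0:
            r, c = np.unravel_index(int(np.argmin(self.values)), self.values.shape)
            raise DataFormatError(
                f"negative expression value {self.values[r, c]} at "
                f"cell '{self.cell_ids[r]}', gene '{self.gene_ids[c]}'"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Column subset (and reorder) by gene identifier."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        cols = [idx[g] for g in genes]
        return ExpressionMatrix(self.values[:, cols], list(genes), list(self.cell_ids))


@dataclass
class LabelVector:
    """Per-cell categorical class label, aligned to a cell ordering."""

    labels: np.ndarray
    classes: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray([str(v) for v in np.asarray(self.labels).ravel()], dtype=object)
        if self.classes is None:
            self.classes = sorted(set(self.labels))
        self.classes = [str(c) for c in self.classes]
        if len(self.classes) < 2:
            raise DataFormatError("≥2 classes required")
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise DataFormatError(f"labels outside declared classes: {sorted(unknown)[:5]}")

    def __len__(self) -> int:
        return len(self.labels)

    def class_sizes(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.classes}


@dataclass
class RankedFeatureList:
    """Features ordered by non-increasing relative-importance score."""

    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        self.entries = [(str(g), float(s)) for g, s in self.entries]
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            raise DataFormatError("duplicate gene in ranked feature list")
        scores = [s for _, s in self.entries]
        if any(b > a + 1e-12 for a, b in zip(scores, scores[1:])):
            raise DataFormatError("RI scores must be non-increasing")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# readers


def _read_sidecar_ids(path: Path) -> list[str]:
    if not path.exists():
        raise DataFormatError(f"missing sidecar file: {path}")
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_expression(path: str | os.PathLike, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from MatrixMarket (plus ``genes.tsv`` /
    ``barcodes.tsv`` sidecars) or dense TSV.

    MTX inputs stored genes × cells are detected from the sidecar lengths
    and transposed to the canonical cells × genes orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "mtx":
        genes = _read_sidecar_ids(path.parent / "genes.tsv")
        cells = _read_sidecar_ids(path.parent / "barcodes.tsv")
        m = scipy.io.mmread(path)
        if scipy.sparse.issparse(m):
            m = m.toarray()
        m = np.asarray(m, dtype=float)
        if m.shape == (len(cells), len(genes)):
            pass
        elif m.shape == (len(genes), len(cells)):
            m = m.T
        else:
            raise DataFormatError(
                f"{path}: matrix shape {m.shape} matches neither "
                f"(cells={len(cells)}, genes={len(genes)}) nor its transpose"
            )
        return ExpressionMatrix(m, genes, cells)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as e:
            raise DataFormatError(f"{path}: non-numeric expression value ({e})") from e
        return ExpressionMatrix(values, [str(c) for c in df.columns], [str(i) for i in df.index])
    raise ValueError(f"unknown format {format!r}")


def read_labels(path: str | os.PathLike, cell_ids: Sequence[str] | None = None) -> LabelVector:
    """Read a two-column (cell_id, label) TSV, optionally re-ordered to match
    a supplied cell ordering.  A first line whose first field is ``cell_id``
    is treated as a header."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataFormatError(f"{path}:{i + 1}: expected two tab-separated columns")
            if i == 0 and parts[0].lower() in ("cell_id", "cell", "barcode"):
                continue
            rows.append((parts[0], parts[1]))
    mapping: dict[str, str] = {}
    for cid, lab in rows:
        if cid in mapping and mapping[cid] != lab:
            raise DataFormatError(f"{path}: conflicting labels for cell '{cid}'")
        mapping[cid] = lab
    if cell_ids is not None:
        missing = [c for c in cell_ids if c not in mapping]
        if missing:
            raise DataFormatError(
                f"{path}: {len(missing)} cells missing from label file: {missing[:5]}"
            )
        labels = [mapping[c] for c in cell_ids]
    else:
        seen: set[str] = set()
        labels = []
        for cid, _ in rows:
            if cid not in seen:
                seen.add(cid)
                labels.append(mapping[cid])
    return LabelVector(np.asarray(labels, dtype=object))


def read_ranked_features(path: str | os.PathLike) -> RankedFeatureList:
    df = pd.read_csv(path, sep="\t")
    return RankedFeatureList(list(zip(df["gene"].astype(str), df["RI"].astype(float))))


def read_ifs_curve(path: str | os.PathLike):
    from .ifs import IFSCurve, IFSRecord  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t")
    meta_cols = {"n_features", "mcc", "acc"}
    class_cols = [c for c in df.columns if c not in meta_cols]
    records = [
        IFSRecord(
            n_features=int(r["n_features"]),
            mcc=float(r["mcc"]),
            acc=float(r["acc"]),
            per_class={c: float(r[c]) for c in class_cols},
        )
        for _, r in df.iterrows()
    ]
    with open(Path(path).with_suffix(".meta.json")) as fh:
        meta = json.load(fh)
    return IFSCurve(records=records, optimal_k=meta["optimal_k"], efficient_k=meta["efficient_k"])


def read_rules(path: str | os.PathLike):
    from .rules import DecisionRule, RuleSet

    with open(path) as fh:
        doc = json.load(fh)
    rules = [
        DecisionRule(
            conditions=[(c["gene"], c["op"], float(c["threshold"])) for c in r["conditions"]],
            predicted_class=r["predicted_class"],
            support=int(r["support"]),
            confidence=float(r["confidence"]),
        )
        for r in doc["rules"]
    ]
    return RuleSet(rules=rules, n_extracted=int(doc["n_extracted"]))


# ---------------------------------------------------------------------------
# writers


def write_expression_tsv(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.cell_ids, columns=matrix.gene_ids)
    df.index.name = "cell_id"
    df.to_csv(path, sep="\t")


def write_expression_mtx(matrix: ExpressionMatrix, path: str | os.PathLike) -> None:
    """Write cells × genes sparse MTX plus genes.tsv / barcodes.tsv sidecars."""
    path = Path(path)
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix.values))
    (path.parent / "genes.tsv").write_text("".join(g + "\n" for g in matrix.gene_ids))
    (path.parent / "barcodes.tsv").write_text("".join(c + "\n" for c in matrix.cell_ids))


def write_labels(labels: LabelVector, cell_ids: Sequence[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tlabel\n")
        for cid, lab in zip(cell_ids, labels.labels):
            fh.write(f"{cid}\t{lab}\n")


def write_ranked_features(ranked: RankedFeatureList, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(ranked) + 1),
            "gene": ranked.gene_ids,
            "RI": [s for _, s in ranked.entries],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_ifs_curve(curve, path: str | os.PathLike) -> None:
    path = Path(path)
    classes = list(curve.records[0].per_class) if curve.records else []
    rows = [
        {"n_features": r.n_features, "mcc": r.mcc, "acc": r.acc, **{c: r.per_class[c] for c in classes}}
        for r in curve.records
    ]
    pd.DataFrame(rows, columns=["n_features", "mcc", "acc", *classes]).to_csv(
        path, sep="\t", index=False
    )
    with open(path.with_suffix(".meta.json"), "w") as fh:
        json.dump({"optimal_k": curve.optimal_k, "efficient_k": curve.efficient_k}, fh, indent=1)
        fh.write("\n")


def write_rules(rules, json_path: str | os.PathLike, txt_path: str | os.PathLike | None = None) -> None:
    doc = {
        "n_extracted": rules.n_extracted,
        "rules": [
            {
                "conditions": [
                    {"gene": g, "op": op, "threshold": thr} for g, op, thr in r.conditions
                ],
                "predicted_class": r.predicted_class,
                "support": r.support,
                "confidence": r.confidence,
            }
            for r in rules.rules
        ],
    }
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
    if txt_path is not None:
        with open(txt_path, "w") as fh:
            for i, r in enumerate(rules.rules[: rules.n_extracted], 1):
                if r.conditions:
                    cond = " AND ".join(f"{g} {op} {thr:.4g}" for g, op, thr in r.conditions)
                else:
                    cond = "TRUE"
                fh.write(
                    f"{i}. IF {cond} THEN class = {r.predicted_class} "
                    f"(support={r.support}, confidence={r.confidence:.4f})\n"
                )


def write_outputs(ranked, curve, rules, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the three pipeline artifacts to ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ranked_features": out / "ranked_features.tsv",
        "ifs_curve": out / "ifs_curve.tsv",
        "rules_json": out / "rules.json",
        "rules_txt": out / "rules.txt",
    }
    write_ranked_features(ranked, paths["ranked_features"])
    write_ifs_curve(curve, paths["ifs_curve"])
    write_rules(rules, paths["rules_json"], paths["rules_txt"])
    return paths
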