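"""TSV / GMT readers and writers.

Expression matrices travel as TSV with genes as rows (first column
``gene_id``) and samples as columns, accompanied by a sample sheet TSV with
columns ``sample_id``, ``class`` (case/control) and ``batch``. Gene sets use
the GMT convention: term, description, then tab-separated member gene ids.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import DataError, ExpressionMatrix


def write_expression(m: ExpressionMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.expr.tsv`` and ``<prefix>.samples.tsv``; returns both paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    expr_path = prefix.with_name(prefix.name + ".expr.tsv")
    sheet_path = prefix.with_name(prefix.name + ".samples.tsv")
    df = m.values.copy()
    df.index.name = "gene_id"
    df.to_csv(expr_path, sep="\t")
    sheet = pd.DataFrame(
        {"sample_id": m.sample_ids, "class": m.classes.to_numpy(), "batch": m.batches.to_numpy()}
    )
    sheet.to_csv(sheet_path, sep="\t", index=False)
    return expr_path, sheet_path


def read_expression(expr_path: str | Path, sheet_path: str | Path, scale: str = "log2") -> ExpressionMatrix:
    # round_trip parsing keeps the TSV <-> memory cycle bit-exact
    df = pd.read_csv(expr_path, sep="\t", index_col=0, float_precision="round_trip")
    sheet = pd.read_csv(sheet_path, sep="\t", dtype={"batch": str})
    required = {"sample_id", "class", "batch"}
    if not required.issubset(sheet.columns):
        raise DataError(f"sample sheet must have columns {sorted(required)}")
    sheet = sheet.set_index("sample_id")
    missing = [s for s in df.columns if s not in sheet.index]
    if missing:
        raise DataError(f"samples missing from sheet: {missing[:5]}")
    return ExpressionMatrix(
        values=df,
        classes=sheet["class"].reindex(df.columns),
        batches=sheet["batch"].reindex(df.columns),
        scale=scale,
    )


def write_gmt(annotation: dict[str, list[str]], path: str | Path, descriptions: dict[str, str] | None = None) -> Path:
    """Write a term -> member-genes mapping as GMT."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term in annotation:
            desc = descriptions.get(term, "na")
            fh.write("\t".join([term, desc, *annotation[term]]) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    annotation: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            annotation[parts[0]] = [g for g in parts[2:] if g]
    return annotation
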