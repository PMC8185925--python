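"""Reading and writing the three input tables.

CSV or TSV (by extension), header row, first column the sample or
metabolite ID.  Empty strings and "NA" parse as missing; "NA" is
written for missing cells.  Validation is exhaustive: duplicate IDs,
abundance/metadata sample mismatches, non-numeric abundance cells and
unknown categorical levels are reported with the offending IDs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from rametab.covariates import encode_sex, encode_smoking

__all__ = ["read_tables", "write_tables", "read_table"]

_NA_VALUES = ["", "NA"]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(path), index_col=0,
                       na_values=_NA_VALUES, keep_default_na=False)


def read_tables(abundance_path, metadata_path, annotation_path
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load and cross-validate abundance, metadata and annotation tables."""
    abundance = read_table(abundance_path)
    meta = read_table(metadata_path)
    annotation = read_table(annotation_path)

    problems = []
    for name, frame in (("abundance", abundance), ("metadata", meta)):
        dup = frame.index[frame.index.duplicated()].unique().tolist()
        if dup:
            problems.append(f"duplicate sample IDs in {name}: {dup}")
    dup = annotation.index[annotation.index.duplicated()].unique().tolist()
    if dup:
        problems.append(f"duplicate metabolite IDs in annotation: {dup}")
    dupc = abundance.columns[abundance.columns.duplicated()].unique().tolist()
    if dupc:
        problems.append(f"duplicate metabolite IDs in abundance: {dupc}")

    orphan_ab = abundance.index.difference(meta.index).tolist()
    orphan_meta = meta.index.difference(abundance.index).tolist()
    if orphan_ab:
        problems.append(f"abundance samples absent from metadata: {orphan_ab}")
    if orphan_meta:
        problems.append(f"metadata samples absent from abundance: {orphan_meta}")

    non_numeric = [c for c in abundance.columns
                   if not np.issubdtype(abundance[c].dtype, np.number)]
    if non_numeric:
        problems.append(
            f"non-numeric abundance cells in metabolites: {non_numeric[:10]}")
    if problems:
        raise ValueError("input validation failed:\n- " + "\n- ".join(problems))

    # categorical levels checked eagerly so modeling never meets them
    encode_sex(meta["sex"])
    if "smoking" in meta:
        encode_smoking(meta["smoking"])
    meta = meta.loc[abundance.index]
    return abundance, meta, annotation


def write_tables(outdir, abundance: pd.DataFrame, meta: pd.DataFrame,
                 annotation: pd.DataFrame, fmt: str = "csv") -> dict[str, Path]:
    """Write the three tables; returns {name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sep = "\t" if fmt == "tsv" else ","
    paths = {}
    for name, frame in (("abundance", abundance), ("metadata", meta),
                        ("annotation", annotation)):
        path = outdir / f"{name}.{fmt}"
        frame.to_csv(path, sep=sep, na_rep="NA", float_format="%.10g")
        paths[name] = path
    return paths
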