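"""Tab-separated ingestion and emission of summary-statistic sets.

Two files describe one :class:`~pcssreg.pcss_model.PcssSet`:

* a *means* file with columns ``variable role vtype mean dist_kind
  dist_params`` and a leading comment line ``# n=<sample size>``
  (``dist_params`` is a comma-separated parameter list; empty ``dist_kind``
  means no assumed law);
* a *covariance* file holding the square matrix, with variable names as both
  the header row and the first column.

Write-then-read round-trips reproduce the set exactly (full double
precision).
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pcss_model import PcssError, PcssSet, VariableInfo, distribution_from_spec

__all__ = ["read_pcss", "write_pcss", "read_means_table", "read_cov_table"]


def _parse_n(path: Path) -> int:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("n="):
                    return int(body[2:])
            elif line:
                break
    raise PcssError(f"means file {path} is missing its '# n=<int>' header line")


def read_means_table(path) -> tuple[int, list[VariableInfo], np.ndarray]:
    path = Path(path)
    n = _parse_n(path)
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"dist_params": str}, float_precision="round_trip"
    )
    required = {"variable", "role", "vtype", "mean"}
    if not required.issubset(df.columns):
        raise PcssError(f"means file must have columns {sorted(required)}")
    variables = []
    for _, row in df.iterrows():
        dist = None
        kind = row.get("dist_kind")
        if isinstance(kind, str) and kind and kind.lower() not in ("none", "nan"):
            raw = row.get("dist_params")
            params = [p for p in str(raw).split(",") if p not in ("", "nan")] if pd.notna(raw) else []
            dist = distribution_from_spec(kind, params)
        variables.append(VariableInfo(str(row["variable"]), str(row["role"]), str(row["vtype"]), dist))
    return n, variables, df["mean"].to_numpy(dtype=float)


def read_cov_table(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, float_precision="round_trip")
    names = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != names:
        raise PcssError("covariance file header row and first column disagree")
    return names, df.to_numpy(dtype=float)


def read_pcss(means_path, cov_path, validate: bool = True) -> PcssSet:
    """Load a summary-statistic set from its means and covariance files."""
    n, variables, means = read_means_table(means_path)
    names, cov = read_cov_table(cov_path)
    order = [v.name for v in variables]
    if set(names) != set(order):
        raise PcssError("means and covariance files name different variables")
    if names != order:
        idx = [names.index(nm) for nm in order]
        cov = cov[np.ix_(idx, idx)]
    return PcssSet(n, variables, means, cov, validate=validate)


def write_pcss(pcss: PcssSet, means_path, cov_path) -> None:
    """Emit the two-file dialect read by :func:`read_pcss`."""
    rows = []
    for v, mean in zip(pcss.variables, pcss.means):
        kind, params = "", ""
        if v.distribution is not None:
            kind = v.distribution.kind
            params = ",".join(repr(float(p)) for p in v.distribution.param_values())
        rows.append(
            {
                "variable": v.name,
                "role": v.role,
                "vtype": v.vtype,
                "mean": repr(float(mean)),
                "dist_kind": kind,
                "dist_params": params,
            }
        )
    with open(means_path, "w") as fh:
        fh.write(f"# n={pcss.n}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)

    names = [v.name for v in pcss.variables]
    with open(cov_path, "w") as fh:
        fh.write("\t" + "\t".join(names) + "\n")
        for nm, row in zip(names, pcss.covariance):
            fh.write(nm + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")
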