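"""Study manifests, the replication suite, and report writers.

A study manifest is a CSV with one row per replication test:

    label, condition, r_original, n_original, r_replication, n_replication,
    direction

``r_original``/``n_original`` may be empty (direction-unknown rows, e.g. a
peak found inside a mask of previously significant voxels, for which no
original correlation exists): such rows get a two-sided uniform-prior
analysis only.  ``direction`` is +1, -1, or 0 for two-sided.

All outputs are plain CSV/markdown/JSON; every file starts with a
'#'-prefixed header block carrying the package version, a configuration
hash and the seed where relevant.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

from . import __version__
from .likelihood import StudySummary
from .replication import ReplicationResult, replication_result

__all__ = [
    "load_manifest",
    "builtin_manifest",
    "validate_manifest",
    "run_replication_suite",
    "results_frame",
    "write_table",
    "to_markdown",
    "posterior_curves",
]

_COLUMNS = ["label", "condition", "r_original", "n_original",
            "r_replication", "n_replication", "direction"]


def builtin_manifest() -> pd.DataFrame:
    """The bundled manifest of published original/replication correlation
    pairs (grey-matter volume and occipital GABA tests) used throughout the
    worked examples."""
    with resources.files("replicor.data").joinpath("replication_manifest.csv").open() as fh:
        return load_manifest(fh)


def load_manifest(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, comment="#")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    validate_manifest(df)
    return df


def validate_manifest(df: pd.DataFrame) -> None:
    """Raise with row numbers on inconsistent rows."""
    problems = []
    for i, row in df.iterrows():
        d = row["direction"]
        if d not in (-1, 0, 1):
            problems.append(f"row {i}: direction must be -1, 0 or 1 (got {d!r})")
        if np.isfinite(row.get("r_original", np.nan)):
            if d != 0 and np.sign(row["r_original"]) != d:
                problems.append(
                    f"row {i}: direction {d} inconsistent with sign of "
                    f"r_original={row['r_original']}")
            if not np.isfinite(row.get("n_original", np.nan)):
                problems.append(f"row {i}: r_original given without n_original")
    if problems:
        raise ValueError("invalid manifest:\n" + "\n".join(problems))


def _row_studies(row) -> tuple[StudySummary | None, StudySummary]:
    label = f"{row['label']} ({row['condition']})"
    direction = int(row["direction"])
    replication = StudySummary(
        r_obs=float(row["r_replication"]), n=int(row["n_replication"]),
        direction=direction, label=label)
    if np.isfinite(row.get("r_original", np.nan)):
        original = StudySummary(
            r_obs=float(row["r_original"]), n=int(row["n_original"]),
            direction=direction, label=label + " [original]")
    else:
        original = None
    return original, replication


def run_replication_suite(manifest: pd.DataFrame
                          ) -> tuple[list[ReplicationResult], list[str]]:
    """Run the full Bayesian replication analysis for every manifest row.

    Returns (results, errors); malformed rows are reported with their row
    number and skipped, so partial results are still produced.
    """
    results, errors = [], []
    for i, row in manifest.iterrows():
        try:
            original, replication = _row_studies(row)
            results.append(replication_result(original, replication))
        except (ValueError, KeyError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    return results, errors


def results_frame(results: list[ReplicationResult]) -> pd.DataFrame:
    """Tabular report: label, both BFs (and their reciprocals), MAP,
    credible interval and evidence categories, one row per test."""
    rows = []
    for res in results:
        rows.append({
            "label": res.label,
            "bf10_uniform": res.bf10_uniform,
            "bf01_uniform": 1.0 / res.bf10_uniform,
            "bf10_informed": res.bf10_informed,
            "bf01_informed": None if res.bf10_informed is None
                             else 1.0 / res.bf10_informed,
            "map": res.map,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "evidence_uniform": res.evidence_uniform,
            "evidence_informed": res.evidence_informed,
        })
    return pd.DataFrame(rows)


def posterior_curves(results: list[ReplicationResult]) -> pd.DataFrame:
    """Long-format posterior curves (label, rho, density) for plotting."""
    frames = [pd.DataFrame({"label": res.label, "rho": res.posterior.nodes,
                            "density": res.posterior.density})
              for res in results]
    return pd.concat(frames, ignore_index=True)


def _config_hash(params: dict) -> str:
    blob = repr(sorted(params.items())).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def header_block(params: dict, seed: int | None = None) -> str:
    lines = [f"# replicor {__version__}", f"# config_hash: {_config_hash(params)}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, params: dict | None = None,
                seed: int | None = None, float_format: str = "%.6g") -> None:
    """CSV writer with the standard header block (read back with
    ``pd.read_csv(..., comment='#')``)."""
    with open(path, "w", newline="") as fh:
        fh.write(header_block(params or {}, seed))
        df.to_csv(fh, index=False, float_format=float_format)


def _sig3(v) -> str:
    return "" if v is None or (isinstance(v, float) and not np.isfinite(v)) \
        else f"{v:.3g}"


def to_markdown(df: pd.DataFrame) -> str:
    """Markdown rendering of a replication results table (BFs to 3
    significant figures, MAP/CI to 3 decimals)."""
    out = df.copy()
    for col in ("bf10_uniform", "bf01_uniform", "bf10_informed", "bf01_informed"):
        if col in out:
            out[col] = out[col].map(_sig3)
    for col in ("map", "ci_low", "ci_high"):
        if col in out:
            out[col] = out[col].map(lambda v: f"{v:.3f}")
    return out.to_markdown(index=False)
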