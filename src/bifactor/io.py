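"""Reading and writing matrices, result records, and scenario files.

All artifacts are plain text: delimited matrices at full double precision
(17 significant digits, so write-then-read round-trips are lossless), JSON
for structures and result metadata, and YAML for simulation scenarios.
Variable indices in every output are 1-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import SampleCovariance
from .simulate import SimulationDesign
from .structure import BiFactorStructure

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_sample",
    "write_structure",
    "read_structure",
    "write_result_record",
    "read_result_record",
    "load_scenario",
]

_FLOAT_FMT = "%.17g"


def write_matrix(path, M: np.ndarray, header: list[str] | None = None, sep: str = ",") -> None:
    """Write a matrix as delimited text at full double precision."""
    path = Path(path)
    with path.open("w") as fh:
        if header is not None:
            fh.write(sep.join(header) + "\n")
        np.savetxt(fh, np.atleast_2d(M), fmt=_FLOAT_FMT, delimiter=sep)


def _sniff_sep(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def read_matrix(path) -> tuple[np.ndarray, list[str] | None]:
    """Read a delimited numeric matrix; returns (values, header or None).

    Accepts comma- or tab-delimited text with an optional single header row
    of variable names.  Malformed cells raise with the row/column position.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: file is empty")
    sep = _sniff_sep(first)
    tokens = first.strip().split(sep)
    has_header = False
    for tok in tokens:
        try:
            float(tok)
        except ValueError:
            has_header = True
            break
    header = [t.strip() for t in tokens] if has_header else None
    rows: list[list[float]] = []
    with path.open() as fh:
        for i, line in enumerate(fh):
            if i == 0 and has_header:
                continue
            if not line.strip():
                continue
            vals = []
            for c, tok in enumerate(line.strip().split(sep)):
                try:
                    vals.append(float(tok))
                except ValueError:
                    raise ValueError(
                        f"{path}: cannot parse {tok!r} at row {i + 1}, column {c + 1}"
                    ) from None
            rows.append(vals)
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows with widths {sorted(widths)}")
    return np.asarray(rows, dtype=float), header


def read_sample(
    path,
    kind: str = "data",
    n_obs: int | None = None,
    denominator: str = "ml",
) -> tuple[SampleCovariance, list[str] | None]:
    """Load the solver input from delimited text.

    ``kind='data'`` expects N x J raw observations; ``'covariance'`` or
    ``'correlation'`` expects a J x J matrix, with ``n_obs`` supplied.
    """
    M, header = read_matrix(path)
    if kind == "data":
        return SampleCovariance.from_data(M, denominator=denominator), header
    if kind in ("covariance", "correlation"):
        if n_obs is None:
            raise ValueError("n_obs is required for covariance/correlation input")
        return (
            SampleCovariance(S=M, N=int(n_obs), is_correlation=kind == "correlation"),
            header,
        )
    raise ValueError(f"unknown input kind {kind!r}")


def write_structure(path, structure: BiFactorStructure) -> None:
    Path(path).write_text(json.dumps(structure.to_dict(), indent=1) + "\n")


def read_structure(path) -> BiFactorStructure:
    return BiFactorStructure.from_dict(json.loads(Path(path).read_text()))


def write_result_record(outdir, results, seed: int, config_echo: dict | None = None) -> None:
    """Persist a fit: loadings/phi/psi as CSV, structure as JSON, metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(outdir / "loadings.csv", results.loadings.to_numpy(),
                 header=list(results.loadings.columns))
    write_matrix(outdir / "phi.csv", results.factor_corr.to_numpy(),
                 header=list(results.factor_corr.columns))
    write_matrix(outdir / "psi.csv", results.uniquenesses.to_numpy()[None, :],
                 header=list(results.uniquenesses.index))
    if results.structure is not None:
        write_structure(outdir / "structure.json", results.structure)
    hist = results.raw.diagnostics
    if hist:
        cols = list(hist[0])
        rows = np.array([[row[c] for c in cols] for row in hist], dtype=float)
        write_matrix(outdir / "history.csv", rows, header=cols)
    meta = {
        "loss": results.loss,
        "bic": results.bic,
        "converged": bool(results.converged),
        "n_starts": results.raw.n_starts_used,
        "restarts_used": results.raw.restarts_used,
        "distance_to_bifactor": results.distance_to_bifactor,
        "seed": seed,
        "version": __version__,
        "config": config_echo or {},
    }
    (outdir / "result.json").write_text(json.dumps(meta, indent=1) + "\n")


def read_result_record(outdir) -> dict:
    outdir = Path(outdir)
    out = json.loads((outdir / "result.json").read_text())
    out["loadings"], _ = read_matrix(outdir / "loadings.csv")
    out["phi"], _ = read_matrix(outdir / "phi.csv")
    psi, _ = read_matrix(outdir / "psi.csv")
    out["psi"] = psi.ravel()
    spath = outdir / "structure.json"
    if spath.exists():
        out["structure"] = read_structure(spath)
    return out


def load_scenario(path) -> dict:
    """Load a simulation scenario YAML.

    Required keys: design fields (J, G, N, ...), ``n_replications``.
    Optional: ``model_seed`` (default 0), ``data_seed_base`` (default 1000),
    ``mechanism`` ('exact' or 'approx'), solver keys ``profile`` and
    ``n_starts``.  Field-level errors name the offending key.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: scenario must be a mapping")
    design_keys = {
        "J", "G", "N", "clusters", "general_range", "group_range",
        "sign_prob", "perturb_range", "beta_range", "psi_value",
    }
    design_kwargs = {}
    for k in design_keys & raw.keys():
        v = raw[k]
        if k.endswith("_range"):
            v = tuple(float(x) for x in v)
        design_kwargs[k] = v
    for k in ("J", "G", "N"):
        if k not in design_kwargs:
            raise ValueError(f"{path}: missing required scenario field {k!r}")
    try:
        design = SimulationDesign(seed=int(raw.get("model_seed", 0)), **design_kwargs)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: invalid design: {err}") from err
    if "n_replications" not in raw:
        raise ValueError(f"{path}: missing required scenario field 'n_replications'")
    return {
        "design": design,
        "n_replications": int(raw["n_replications"]),
        "mechanism": raw.get("mechanism", "exact"),
        "data_seed_base": int(raw.get("data_seed_base", 1000)),
        "profile": raw.get("profile", "simulation"),
        "n_starts": int(raw.get("n_starts", 50)),
    }


def write_truth(outdir, truth) -> None:
    """Sidecar JSON with the true parameters and structure of a replicate."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "loadings": truth.params.loadings.values.tolist(),
        "beta": truth.params.corr_params.beta.tolist(),
        "psi": truth.params.uniq.psi.tolist(),
        "structure": truth.structure.to_dict(),
        "is_exact": bool(truth.is_exact),
    }
    (outdir / "truth.json").write_text(json.dumps(payload) + "\n")


def read_truth(outdir) -> dict:
    payload = json.loads((Path(outdir) / "truth.json").read_text())
    payload["loadings"] = np.asarray(payload["loadings"])
    payload["beta"] = np.asarray(payload["beta"])
    payload["psi"] = np.asarray(payload["psi"])
    payload["structure"] = BiFactorStructure.from_dict(payload["structure"])
    return payload
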