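"""File input/output: counts files, result serialization, run configs.

Counts files are whitespace/newline-separated integers or a single-column
CSV with an optional header; a configurable sentinel (default "NA" or an
empty field) marks missing observations.  Fit results serialize to JSON at
full precision (Python's shortest-round-trip float repr makes re-reading
bit-exact) plus a human-readable CSV summary; CI, decoding, and coverage
results serialize to CSVs shaped like the usual report tables.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .decode import DecodingResult
from .errors import InvalidObservationError
from .fit import FitResult, information_criteria
from .model_core import NaturalParams, ObservationSeries
from .simulate import CoverageStudyResult
from .uncertainty import CIReport

__all__ = [
    "read_counts",
    "write_fit_json",
    "read_fit_json",
    "fit_summary_frame",
    "write_ci_csv",
    "write_decode_csv",
    "write_coverage_csv",
    "write_run_log",
    "RunConfig",
]

DEFAULT_SENTINELS = ("NA", "")


def read_counts(path, missing_sentinels: Sequence[str] = DEFAULT_SENTINELS) -> ObservationSeries:
    """Read a counts series from a text or single-column CSV file."""
    path = Path(path)
    text = path.read_text()
    values = []
    started = False
    for ln, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped == "":
            continue
        tokens = stripped.replace(",", " ").split()
        for col, tok in enumerate(tokens, start=1):
            if tok in missing_sentinels:
                values.append(np.nan)
                started = True
                continue
            try:
                v = float(tok)
            except ValueError:
                if not started:
                    # a single leading non-numeric token is a CSV header
                    started = True
                    continue
                raise InvalidObservationError(
                    f"{path}: non-integer token {tok!r} at line {ln}, column {col}"
                )
            values.append(v)
            started = True
    if not values:
        raise InvalidObservationError(f"{path}: no observations found")
    return ObservationSeries(np.asarray(values, dtype=float))


def _natural_to_dict(params: NaturalParams) -> Dict:
    return {
        "m": params.m,
        "tpm": params.tpm.tolist(),
        "lam": params.lam.tolist(),
        "init": params.init if isinstance(params.init, str) else np.asarray(params.init).tolist(),
    }


def _natural_from_dict(d: Dict) -> NaturalParams:
    init = d["init"]
    return NaturalParams(
        m=int(d["m"]),
        tpm=np.array(d["tpm"], dtype=float),
        lam=np.array(d["lam"], dtype=float),
        init=init if isinstance(init, str) else np.array(init, dtype=float),
    )


def write_fit_json(fit: FitResult, path) -> None:
    """Serialize the fit (full precision) to JSON."""
    aic, bic = information_criteria(fit)
    payload = {
        "m": fit.m,
        "T": fit.T,
        "nll": fit.nll_value,
        "aic": aic,
        "bic": bic,
        "converged": fit.converged,
        "iterations": fit.iterations,
        "gradient_norm": fit.gradient_norm,
        "natural": _natural_to_dict(fit.natural_hat),
        "delta": fit.delta_hat.tolist(),
        "working": fit.working_hat.to_vector().tolist(),
        "constraint_map": list(fit.constraint_map.labels),
        "hessian_working": fit.hessian_working.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fit_json(path) -> Dict:
    """Read a fit JSON back; ``result["natural"]`` is a NaturalParams."""
    d = json.loads(Path(path).read_text())
    d["natural"] = _natural_from_dict(d["natural"])
    return d


def fit_summary_frame(fit: FitResult) -> pd.DataFrame:
    """Parameter estimates in report order as a tidy frame."""
    from .uncertainty import natural_param_names, natural_param_vector

    return pd.DataFrame(
        {
            "parameter": list(natural_param_names(fit.m)),
            "estimate": natural_param_vector(fit.natural_hat),
        }
    )


def write_ci_csv(reports: Dict[str, CIReport], path, round_digits: Optional[int] = None) -> None:
    """Combined CI table: parameter, estimate, <method>_l/<method>_u columns.

    ``reports`` maps method name ("wald", "profile", "bootstrap") to its
    report; methods may cover different parameter subsets (NaN elsewhere).
    Probabilities are clipped to [0, 1] only when rounding for display.
    """
    first = next(iter(reports.values()))
    df = pd.DataFrame({"parameter": list(first.names), "estimate": first.estimates})
    for method, rep in reports.items():
        if tuple(rep.names) != tuple(first.names):
            raise ValueError("CI reports cover different parameter sets")
        lo, hi = rep.lower.copy(), rep.upper.copy()
        if round_digits is not None:
            prob = np.array([not n.startswith("lambda") for n in rep.names])
            lo[prob] = np.clip(lo[prob], 0.0, 1.0)
            hi[prob] = np.clip(hi[prob], 0.0, 1.0)
            lo, hi = np.round(lo, round_digits), np.round(hi, round_digits)
        df[f"{method}_l"] = lo
        df[f"{method}_u"] = hi
    df.to_csv(path, index=False)


def write_decode_csv(obs: ObservationSeries, result: DecodingResult, path) -> None:
    """Decoding table: time, observation, smoothing, paths, conditional mean."""
    T, m = result.smoothing.shape
    data = {"time": np.arange(1, T + 1), "observation": obs.values}
    for i in range(m):
        data[f"smoothing_{i + 1}"] = result.smoothing[:, i]
    data["local_state"] = result.local_path + 1
    data["viterbi_state"] = result.viterbi_path + 1
    data["conditional_mean"] = result.conditional_means
    pd.DataFrame(data).to_csv(path, index=False)


def write_coverage_csv(result: CoverageStudyResult, path) -> None:
    result.to_frame().to_csv(path, index=False)


def write_run_log(path, seed=None, options: Optional[Dict] = None) -> None:
    """Record seed, options, and versions next to every run's outputs."""
    import poishmm

    payload = {
        "poishmm_version": poishmm.__version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "seed": seed,
        "options": options or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class RunConfig:
    """Plain-text run configuration (key = value lines).

    CLI flags override file values; unknown keys raise.
    """

    data: Optional[str] = None
    states: int = 2
    level: float = 0.95
    methods: Tuple[str, ...] = ("wald",)
    B: int = 1000
    M: int = 100
    T: int = 2000
    seed: Optional[int] = None
    out_dir: str = "."
    verbose: int = 0

    _CASTS = {
        "states": int, "B": int, "M": int, "T": int, "seed": int, "verbose": int,
        "level": float,
    }

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        cfg = cls()
        for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if "=" not in s:
                raise ValueError(f"{path}:{ln}: expected key = value")
            key, _, value = s.partition("=")
            key, value = key.strip(), value.strip()
            if not hasattr(cfg, key) or key.startswith("_"):
                raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
            if key == "methods":
                setattr(cfg, key, tuple(v.strip() for v in value.split(",") if v.strip()))
            elif key in cls._CASTS:
                setattr(cfg, key, cls._CASTS[key](value))
            else:
                setattr(cfg, key, value)
        return cfg

    def to_file(self, path) -> None:
        lines = []
        for key, value in asdict(self).items():
            if key.startswith("_") or value is None:
                continue
            if isinstance(value, tuple):
                value = ",".join(value)
            lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")
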