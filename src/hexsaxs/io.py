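"""Pattern I/O, run configuration and output provenance.

Scattering patterns travel as plain three-column text (q [1/A], intensity
[arb. u.], standard deviation), with ``#`` comment lines; ``key = value``
comments in the header are parsed into the pattern metadata.  Writers
emit the same format, so read/write round-trips are value-identical.
Run configurations are YAML-backed and hashed (SHA-256 of the canonical
JSON form) so every output artifact can record exactly what produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "ScatteringPattern",
    "RunConfig",
    "read_pattern",
    "write_pattern",
    "config_hash",
]

log = logging.getLogger(__name__)


@dataclass
class ScatteringPattern:
    """A 1D powder pattern: (q, I_obs, sigma) triplets plus metadata.

    Invariants: equal lengths; q strictly increasing and positive;
    sigma positive for every fitted point.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.size == self.intensity.size == self.sigma.size):
            raise ValueError("q, intensity and sigma must have equal lengths")
        if self.q.size and (np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0)):
            raise ValueError("q must be strictly increasing and positive")

    def __len__(self) -> int:
        return self.q.size

    def restrict(self, q_min: float, q_max: float) -> "ScatteringPattern":
        """Sub-pattern with q_min <= q <= q_max (metadata shared)."""
        m = (self.q >= q_min) & (self.q <= q_max)
        return ScatteringPattern(
            q=self.q[m], intensity=self.intensity[m], sigma=self.sigma[m],
            meta=dict(self.meta),
        )


def _parse_meta_comment(line: str, meta: dict) -> None:
    body = line.lstrip("#").strip()
    for sep in ("=", ":"):
        if sep in body:
            key, _, val = body.partition(sep)
            key, val = key.strip(), val.strip()
            if not key or " " in key:
                return
            try:
                meta[key] = json.loads(val)
            except (json.JSONDecodeError, ValueError):
                meta[key] = val
            return


def read_pattern(
    path: str | Path,
    *,
    q_unit: str = "1/A",
) -> ScatteringPattern:
    """Read a three-column text pattern (q, I, sigma).

    Comment lines start with ``#``; header comments of the form
    ``# key = value`` populate the metadata.  Rows with non-positive q or
    sigma are dropped (with a logged count), a descending q axis is
    reordered ascending (with a warning).  ``q_unit="1/nm"`` converts the
    q column to 1/A.
    """
    path = Path(path)
    if q_unit not in ("1/A", "1/nm"):
        raise ValueError(f"unknown q unit {q_unit!r}")
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                _parse_meta_comment(line, meta)
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{ln}: expected >= 3 columns (q, I, sigma), "
                    f"got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts[:3]])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-numeric data {line!r}") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows)
    if q_unit == "1/nm":
        arr[:, 0] /= 10.0
    keep = (arr[:, 0] > 0) & (arr[:, 2] > 0)
    if not np.all(keep):
        log.warning(
            "%s: dropped %d row(s) with non-positive q or sigma",
            path, int(np.sum(~keep)),
        )
        arr = arr[keep]
    if arr.shape[0] == 0:
        raise ValueError(f"{path}: no valid data rows after filtering")
    if np.any(np.diff(arr[:, 0]) < 0):
        warnings.warn(f"{path}: q not ascending; reordering", stacklevel=2)
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
    return ScatteringPattern(
        q=arr[:, 0], intensity=arr[:, 1], sigma=arr[:, 2], meta=meta
    )


def write_pattern(pattern: ScatteringPattern, path: str | Path) -> None:
    """Write a pattern in the three-column text format (with metadata header).

    Nested metadata (e.g. the ground-truth sidecar of synthetic patterns)
    is JSON-encoded in the comment value, so round-trips preserve it.
    """
    path = Path(path)
    lines = ["# hexsaxs pattern: q [1/A]  intensity [arb. u.]  sigma"]
    for key, val in pattern.meta.items():
        lines.append(f"# {key} = {json.dumps(val, default=float)}")
    for qi, ii, si in zip(pattern.q, pattern.intensity, pattern.sigma):
        lines.append(f"{qi:.8e} {ii:.8e} {si:.8e}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Validated, hashable configuration of a fit run.

    Bundles the lipid choice, prior-box overrides, sampler settings,
    quadrature settings and the fitted q range; ``hash()`` (SHA-256 of
    canonical JSON) is recorded in every output artifact.
    """

    lipid: str = "DOPE"
    a: float | None = None
    q_min: float = 0.05
    q_max: float = 0.5
    n_steps: int = 20_000
    burn_in_frac: float = 0.2
    seed: int = 0
    proposal_frac: float = 0.02
    tune_steps: int = 3_000
    pilot_steps: int = 4_000
    thin: int | str = "auto"
    explicit_eta: bool = False
    fixed: tuple[str, ...] = ()
    bounds_overrides: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    qs_oversample: int = 2
    low_qs_points: int = 48
    n_smear: int = 15
    x0: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.q_min < self.q_max:
            raise ValueError("need 0 < q_min < q_max")
        if self.n_steps < 1:
            raise ValueError("n_steps must be positive")
        if not 0.1 <= self.burn_in_frac <= 0.2:
            raise ValueError("burn_in_frac must lie in [0.1, 0.2]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "fixed" in raw:
            raw["fixed"] = tuple(raw["fixed"])
        if "bounds_overrides" in raw:
            raw["bounds_overrides"] = {
                k: tuple(v) for k, v in raw["bounds_overrides"].items()
            }
        return cls(**raw)

    def to_dict(self) -> dict:
        out = {}
        for k in self.__dataclass_fields__:
            v = getattr(self, k)
            if isinstance(v, tuple):
                v = list(v)
            elif isinstance(v, Mapping):
                v = {kk: list(vv) if isinstance(vv, tuple) else vv
                     for kk, vv in v.items()}
            out[k] = v
        return out

    def hash(self) -> str:
        return config_hash(self.to_dict())

    def fit_config(self, pattern: ScatteringPattern | None = None):
        """Build the :class:`hexsaxs.inference.FitConfig` for this run."""
        from .inference import FitConfig, PriorBounds
        from .scattering import ModelParams, QuadratureSettings

        bounds = PriorBounds()
        if self.bounds_overrides:
            bounds = bounds.replace(**dict(self.bounds_overrides))
        x0 = ModelParams(**dict(self.x0)) if self.x0 is not None else None
        a = self.a
        if a is None and pattern is not None:
            a = pattern.meta.get("a")
        return FitConfig(
            lipid=self.lipid,
            a=a,
            n_steps=self.n_steps,
            burn_in_frac=self.burn_in_frac,
            seed=self.seed,
            x0=x0,
            proposal_frac=self.proposal_frac,
            tune_steps=self.tune_steps,
            pilot_steps=self.pilot_steps,
            thin=self.thin,
            explicit_eta=self.explicit_eta,
            fixed=tuple(self.fixed),
            settings=QuadratureSettings(
                qs_oversample=self.qs_oversample,
                low_qs_points=self.low_qs_points,
                n_smear=self.n_smear,
            ),
            bounds=bounds,
        )


def config_hash(obj) -> str:
    """SHA-256 hex digest of the canonical JSON form of a configuration."""
    blob = json.dumps(obj, sort_keys=True, separators=(",", ":"), default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
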