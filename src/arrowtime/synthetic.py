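"""Ground-truth cohort generators for exercising the full pipeline.

Cohorts are simulated from a stable VAR(1), x_t = A x_{t-1} + e_t, with
innovations drawn from a configurable family per region (standardized to
unit variance so that kurtosis is the only family difference), a burn-in
discarded, and each subject z-scored — mirroring how real parcellated data
enter the pipeline.

Causal roles are encoded in the sparsity of A: a *source* has only outgoing
couplings, a *sink* only incoming ones.  By default the chain builder drives
source regions with Gaussian innovations and the downstream regions with the
requested non-Gaussian family.  This heterogeneity is what lets the sign of
the arrow-of-time statistic recover the roles: with homogeneous innovations
every backward residual is a mixture whose |excess kurtosis| cannot exceed
the forward one, so all regions come out nonnegative and sources are not
sign-separable.  A Gaussian-driven source instead inherits its target's
non-Gaussianity only backward in time and turns genuinely negative.

An optional modulation window rescales selected couplings by a multiplicative
gain inside a time interval, emulating paradigm-locked coupling changes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import gamma as gamma_fn
from scipy.stats import gennorm

from .data_model import SubjectSeries, write_subject_tsv, zscore_regions

__all__ = [
    "Modulation",
    "SyntheticSystem",
    "make_chain_system",
    "simulate_cohort",
    "write_cohort",
]

BURN_IN_DEFAULT = 200  # samples discarded to reach stationarity


@dataclass
class Modulation:
    """Multiplicative gain on selected couplings inside [start, stop).

    Times are in post-burn-in sample indices; ``edges`` lists (from, to)
    region pairs whose coupling A[to, from] is scaled by ``gain`` while the
    window is active.
    """

    start: int
    stop: int
    gain: float
    edges: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("modulation window must have stop > start")


@dataclass
class SyntheticSystem:
    """A stable VAR(1) generator with labelled causal roles.

    ``families`` holds one innovation family per region: ``"gaussian"``,
    ``"laplace"``, ``("student_t", df)`` or ``("generalized_gaussian",
    shape)``.  ``roles`` are derived from the off-diagonal sparsity of A.
    """

    A: np.ndarray
    families: list
    roles: list[str]
    scales: np.ndarray | None = None
    modulation: Modulation | None = None
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        radius = float(np.abs(np.linalg.eigvals(self.A)).max())
        if radius >= 1:
            raise ValueError(f"unstable system: spectral radius {radius:.3f} >= 1")
        if self.modulation is not None:
            mod_A = self.modulated_A()
            mod_radius = float(np.abs(np.linalg.eigvals(mod_A)).max())
            if mod_radius >= 1:
                raise ValueError(
                    f"unstable modulated system: spectral radius {mod_radius:.3f} >= 1"
                )
        if self.scales is None:
            self.scales = np.ones(n)
        self.scales = np.asarray(self.scales, dtype=float)
        if len(self.families) != n or len(self.roles) != n or self.scales.size != n:
            raise ValueError("families, roles and scales must have one entry per region")
        if not self.region_ids:
            self.region_ids = [f"r{i:03d}" for i in range(n)]

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.abs(np.linalg.eigvals(self.A)).max())

    def modulated_A(self) -> np.ndarray:
        if self.modulation is None:
            return self.A
        A = self.A.copy()
        for i, j in self.modulation.edges:
            A[j, i] *= self.modulation.gain
        return A


def roles_from_edges(n_regions: int, edges: Sequence[tuple[int, int]]) -> list[str]:
    """Derive source/relay/sink/isolated roles from a directed edge set."""
    outs = {i for i, _ in edges}
    ins = {j for _, j in edges}
    roles = []
    for r in range(n_regions):
        if r in outs and r in ins:
            roles.append("relay")
        elif r in outs:
            roles.append("source")
        elif r in ins:
            roles.append("sink")
        else:
            roles.append("isolated")
    return roles


def make_chain_system(
    n_regions: int,
    edges: Sequence[tuple[int, int]] | None = None,
    family: str | tuple = "laplace",
    coupling: float = 1.2,
    self_coupling: float = 0.3,
    source_family: str | tuple | None = "gaussian",
    modulation: Modulation | None = None,
) -> SyntheticSystem:
    """Build a causal-chain VAR(1) with labelled source/relay/sink roles.

    ``edges`` defaults to the sequential chain 0 -> 1 -> ... -> n-1; each
    edge (i, j) sets A[j, i] = coupling and every region gets a
    ``self_coupling`` diagonal term.  Source regions are driven by
    ``source_family`` (Gaussian by default; pass ``None`` to use ``family``
    everywhere — note that sources are then not sign-separable, see module
    docstring).  Raises with the computed spectral radius when the requested
    coefficients are unstable.
    """
    if edges is None:
        edges = [(i, i + 1) for i in range(n_regions - 1)]
    edges = [tuple(e) for e in edges]
    A = np.diag(np.full(n_regions, float(self_coupling)))
    for i, j in edges:
        A[j, i] = coupling
    roles = roles_from_edges(n_regions, edges)
    families = [
        source_family if (role == "source" and source_family is not None) else family
        for role in roles
    ]
    return SyntheticSystem(A=A, families=families, roles=roles, modulation=modulation)


def _standardized_innovations(
    family: str | tuple, size: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance draws from the named family."""
    if isinstance(family, (tuple, list)):
        name, param = family
    else:
        name, param = family, None
    if name == "gaussian":
        return rng.standard_normal(size)
    if name == "laplace":
        return rng.laplace(0.0, 1.0 / math.sqrt(2.0), size)
    if name == "student_t":
        df = float(param)
        if df <= 4:
            raise ValueError("student_t requires df > 4 for finite kurtosis")
        return rng.standard_t(df, size) / math.sqrt(df / (df - 2))
    if name == "generalized_gaussian":
        beta = float(param)
        sd = math.sqrt(gamma_fn(3.0 / beta) / gamma_fn(1.0 / beta))
        return gennorm.rvs(beta, size=size, random_state=rng) / sd
    raise ValueError(f"unknown innovation family {family!r}")


def simulate_cohort(
    system: SyntheticSystem,
    n_subjects: int,
    n_time: int,
    seed: int | np.random.Generator | None = None,
    burn_in: int = BURN_IN_DEFAULT,
    zscore: bool = True,
) -> list[SubjectSeries]:
    """Simulate independent subject realizations of the system.

    Each subject is an independent VAR(1) path started at zero with
    ``burn_in`` initial samples discarded; the modulation window (if any) is
    applied in post-burn-in time.  Subjects are z-scored per region by
    default, as real cohorts are.
    """
    if n_time < 2:
        raise ValueError("n_time must be >= 2")
    rng = np.random.default_rng(seed)
    R = system.n_regions
    total = burn_in + n_time
    eps = np.empty((total, R, n_subjects))
    for i, fam in enumerate(system.families):
        eps[:, i, :] = _standardized_innovations(fam, (total, n_subjects), rng)
    eps *= system.scales[None, :, None]

    A, A_mod = system.A, system.modulated_A()
    mod = system.modulation
    x = np.zeros((R, n_subjects))
    out = np.empty((n_subjects, R, n_time))
    for t in range(total):
        t_out = t - burn_in
        active = mod is not None and mod.start <= t_out < mod.stop
        x = (A_mod if active else A) @ x + eps[t]
        if t_out >= 0:
            out[:, :, t_out] = x.T
    subjects = [
        SubjectSeries(out[s], subject_id=f"sub-{s:03d}", region_ids=list(system.region_ids))
        for s in range(n_subjects)
    ]
    if zscore:
        subjects = [zscore_regions(s) for s in subjects]
    return subjects


def write_cohort(
    subjects: Sequence[SubjectSeries],
    system: SyntheticSystem,
    out_dir: str | Path,
    seed: int | None = None,
) -> None:
    """Write subject TSVs plus a ground-truth JSON (A, roles, seed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        write_subject_tsv(s, out_dir / f"{s.subject_id}.tsv")
    truth = {
        "A_true": system.A.tolist(),
        "roles": system.roles,
        "families": [list(f) if isinstance(f, tuple) else f for f in system.families],
        "region_ids": system.region_ids,
        "seed": seed,
        "modulation": (
            None
            if system.modulation is None
            else {
                "start": system.modulation.start,
                "stop": system.modulation.stop,
                "gain": system.modulation.gain,
                "edges": [list(e) for e in system.modulation.edges],
            }
        ),
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
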