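"""Simulated density datasets: clean sequences, multiplicative noise, splits.

For each benchmark system, 120 density sequences of 50 frames are generated
from randomized initial conditions (the flux system from its analytic Gaussian
solution, bubble and wealth by an RK4 forward solve).  Observations are
modeled with entrywise multiplicative noise, P_noisy = (1 + W xi) P_clean
with xi ~ N(0, 1), and W calibrated so the aggregated relative L2 deviation
of the noisy set from the clean set is ~0.01.  100 sequences train the
inverse method; the remaining 20 are held out to score forecasting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .forward import ExampleSpec, example_spec, example_terms, ou_analytic_density, rk4_solve
from .grid import DerivativeOperators, Grid

__all__ = ["DensitySeries", "Dataset", "sample_initial_condition",
           "generate_sequences", "add_noise", "calibrate_noise", "split_dataset",
           "make_dataset", "aggregate_relative_l2",
           "save_dataset", "load_dataset", "save_dataset_npz", "load_dataset_npz"]


@dataclass
class DensitySeries:
    """One sequence of densities on a fixed grid at uniformly spaced times.

    ``values`` has shape (T, B): row t is the density at time t0 + t*dt.
    """

    values: np.ndarray
    t0: float
    dt: float
    grid: Grid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("a density series needs a (T, B) array with T >= 2")
        if self.values.shape[1] != self.grid.n_bins:
            raise ValueError("series width does not match the grid")
        if not np.isfinite(self.values).all():
            raise ValueError("density series contains non-finite entries")

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    def mass(self) -> np.ndarray:
        """Per-frame integral of the density over the support."""
        return self.values.sum(axis=1) * self.grid.dx


@dataclass
class Dataset:
    """Noisy train/test sequences with their clean counterparts."""

    train: list
    test: list
    clean_train: list
    clean_test: list
    example: ExampleSpec
    noise_w: float
    seed: int


def _draw_ic_params(spec: ExampleSpec, rng: np.random.Generator) -> dict:
    """Random initial-condition parameters per benchmark system."""
    if spec.name == "flux":
        return {"x0": rng.uniform(0.04, 0.08), "t_init": rng.uniform(0.03, 0.05)}
    lo = 0.4 if spec.name == "bubble" else 0.3
    return {"mean": rng.uniform(lo, lo + 0.4), "sd": rng.uniform(0.05, 0.1),
            "t_init": 0.0}


def _ic_density(spec: ExampleSpec, params: dict, at_time: float | None = None) -> np.ndarray:
    """Unit-mass density for drawn IC parameters (flux: analytic frame)."""
    if spec.name == "flux":
        t = params["t_init"] if at_time is None else at_time
        p = ou_analytic_density(spec.parameters["D"], spec.parameters["theta"],
                                params["x0"], t, spec.grid)
    else:
        x = spec.grid.centers
        p = np.exp(-((x - params["mean"]) ** 2) / (2.0 * params["sd"] ** 2))
    return p / (p.sum() * spec.grid.dx)


def sample_initial_condition(spec: ExampleSpec, rng: np.random.Generator):
    """Draw one initial condition for a benchmark system.

    flux: returns the analytic OU density at a random (x0, t_init) with
    x0 ~ U[0.04, 0.08] and t_init ~ U[0.03, 0.05].  bubble / wealth: a
    Gaussian profile with mean ~ U[0.4, 0.8] / U[0.3, 0.7] and standard
    deviation ~ U[0.05, 0.1], at t_init = 0.  The returned density is
    renormalized to unit mass on the grid.
    """
    params = _draw_ic_params(spec, rng)
    return _ic_density(spec, params), params["t_init"]


def generate_sequences(spec: ExampleSpec, n_sequences: int = 120,
                       n_times: int = 50,
                       rng: np.random.Generator | None = None,
                       ops: DerivativeOperators | None = None) -> list:
    """Generate clean density sequences for one benchmark system.

    Flux sequences are evaluated frame-by-frame from the analytic Gaussian
    solution (each frame renormalized to unit grid mass); bubble and wealth
    sequences are advanced by the RK4 forward solve from the sampled initial
    profile.
    """
    rng = np.random.default_rng() if rng is None else rng
    if ops is None and spec.name != "flux":
        ops = DerivativeOperators.build(spec.grid)
    terms = None if spec.name == "flux" else example_terms(spec)
    out = []
    for _ in range(n_sequences):
        params = _draw_ic_params(spec, rng)
        t_init = params["t_init"]
        if spec.name == "flux":
            frames = np.stack([_ic_density(spec, params, t_init + k * spec.dt)
                               for k in range(n_times)])
        else:
            p0 = _ic_density(spec, params)
            frames = rk4_solve(p0, terms, ops, spec.dt, n_times - 1, spec.substeps)
        out.append(DensitySeries(frames, t_init, spec.dt, spec.grid))
    return out


def add_noise(series: DensitySeries, w: float, rng: np.random.Generator) -> DensitySeries:
    """Apply entrywise multiplicative noise (1 + w xi), xi ~ N(0,1).

    Observations are returned as-is: no renormalization and no clipping, so
    small densities may go slightly negative under the noise model.
    """
    if w < 0:
        raise ValueError("noise level w must be nonnegative")
    xi = rng.standard_normal(series.values.shape)
    return replace(series, values=(1.0 + w * xi) * series.values)


def aggregate_relative_l2(noisy: list, clean: list) -> float:
    """Relative L2 deviation with all sequences and frames flattened."""
    num = sum(float(np.sum((a.values - b.values) ** 2)) for a, b in zip(noisy, clean))
    den = sum(float(np.sum(b.values**2)) for b in clean)
    return float(np.sqrt(num / den))


def calibrate_noise(clean: list, target_ratio: float = 0.01,
                    rng: np.random.Generator | None = None) -> float:
    """Find W so the noisy-vs-clean relative L2 deviation matches the target.

    For multiplicative noise the deviation is W times a concentration factor
    that is 1 in expectation; a single pilot draw measures the factor on this
    dataset and rescales W accordingly.
    """
    if target_ratio < 0:
        raise ValueError("target_ratio must be nonnegative")
    if target_ratio == 0.0:
        return 0.0
    rng = np.random.default_rng(0) if rng is None else rng
    pilot = [add_noise(s, target_ratio, rng) for s in clean]
    factor = aggregate_relative_l2(pilot, clean) / target_ratio
    return float(target_ratio / factor)


def split_dataset(series: list, n_train: int = 100,
                  rng: np.random.Generator | None = None):
    """Seeded partition into training and held-out forecasting sequences."""
    if n_train >= len(series):
        raise ValueError(f"n_train={n_train} must be below the {len(series)} "
                         "generated sequences")
    rng = np.random.default_rng(0) if rng is None else rng
    order = rng.permutation(len(series))
    train_idx = np.sort(order[:n_train])
    test_idx = np.sort(order[n_train:])
    return train_idx, test_idx


def make_dataset(spec: ExampleSpec | str, n_sequences: int = 120,
                 n_times: int = 50, n_train: int = 100,
                 target_ratio: float = 0.01, seed: int = 0) -> Dataset:
    """Generate, calibrate, corrupt and split one benchmark dataset."""
    if isinstance(spec, str):
        spec = example_spec(spec)
    rng = np.random.default_rng(seed)
    clean = generate_sequences(spec, n_sequences, n_times, rng)
    w = calibrate_noise(clean, target_ratio, rng)
    noisy = [add_noise(s, w, rng) for s in clean]
    train_idx, test_idx = split_dataset(clean, n_train, rng)
    return Dataset(train=[noisy[i] for i in train_idx],
                   test=[noisy[i] for i in test_idx],
                   clean_train=[clean[i] for i in train_idx],
                   clean_test=[clean[i] for i in test_idx],
                   example=spec, noise_w=w, seed=seed)


# ---------------------------------------------------------------------------
# serialization: TSV-per-series directory with a YAML manifest (text path)
# and a single .npz container (bit-exact binary path)

def _spec_to_dict(spec: ExampleSpec) -> dict:
    return {"name": spec.name, "parameters": dict(spec.parameters),
            "x_min": spec.grid.x_min, "x_max": spec.grid.x_max,
            "n_bins": spec.grid.n_bins, "dt": spec.dt, "substeps": spec.substeps}


def _spec_from_dict(d: dict) -> ExampleSpec:
    return example_spec(d["name"], parameters=d["parameters"],
                        support=(d["x_min"], d["x_max"]), n_bins=d["n_bins"],
                        dt=d["dt"], substeps=d["substeps"])


_GROUPS = ("train", "test", "clean_train", "clean_test")


def save_dataset(dataset: Dataset, directory) -> None:
    """Write one TSV per series (rows = frames, columns = bins) + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"example": _spec_to_dict(dataset.example),
                "noise_w": dataset.noise_w, "seed": dataset.seed, "groups": {}}
    for group in _GROUPS:
        entries = []
        for i, s in enumerate(getattr(dataset, group)):
            fname = f"{group}_{i:03d}.tsv"
            np.savetxt(directory / fname, s.values, delimiter="\t", fmt="%.17g")
            entries.append({"file": fname, "t0": s.t0, "dt": s.dt})
        manifest["groups"][group] = entries
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest))


def load_dataset(directory) -> Dataset:
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    spec = _spec_from_dict(manifest["example"])
    groups = {}
    for group in _GROUPS:
        groups[group] = [
            DensitySeries(np.atleast_2d(np.loadtxt(directory / e["file"], delimiter="\t")),
                          e["t0"], e["dt"], spec.grid)
            for e in manifest["groups"][group]]
    return Dataset(example=spec, noise_w=manifest["noise_w"],
                   seed=manifest["seed"], **groups)


def save_dataset_npz(dataset: Dataset, path) -> None:
    """Single-container binary path; round-trips bit-exactly."""
    arrays = {}
    meta = {"example": _spec_to_dict(dataset.example),
            "noise_w": dataset.noise_w, "seed": dataset.seed, "groups": {}}
    for group in _GROUPS:
        entries = []
        for i, s in enumerate(getattr(dataset, group)):
            key = f"{group}_{i:03d}"
            arrays[key] = s.values
            entries.append({"key": key, "t0": s.t0, "dt": s.dt})
        meta["groups"][group] = entries
    arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)


def load_dataset_npz(path) -> Dataset:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["_meta"]).decode())
        spec = _spec_from_dict(meta["example"])
        groups = {}
        for group in _GROUPS:
            groups[group] = [DensitySeries(npz[e["key"]], e["t0"], e["dt"], spec.grid)
                             for e in meta["groups"][group]]
    return Dataset(example=spec, noise_w=meta["noise_w"], seed=meta["seed"], **groups)
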