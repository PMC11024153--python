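"""Principal gradients, the PGM distance, and transferability maps.

The principal gradient of a dataset is the expectation of feature-extractor
gradients collected over repeated, update-free passes: the model is
(re)initialized, the data is shuffled, and the gradient of the masked loss
with respect to the extractor parameters is accumulated batch by batch — no
optimizer step is ever taken.  The PGM distance between two datasets s, t is

    d(s, t) = || E[grad_t] - E[grad_s] ||_2 / ( ||E[grad_s]||_2 * ||E[grad_t]||_2 )

Smaller distance means more related tasks; the map of all pairwise distances
ranks candidate source datasets for transfer learning.  The measure is
symmetric with a zero diagonal but is not a metric (the normalizing
denominator breaks the triangle inequality), and rescaling both gradients by
c rescales the distance by 1/c.

Restart semantics: by default every restart reuses the same initial point
(``same_init``), so randomness enters only through batch composition;
``random_init`` instead draws a fresh initial point per restart, using the
same paired seeds across datasets so gradients stay comparable.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data_io import MoleculeRecord, TaskSpec, featurize
from .errors import ComparabilityError, ConfigurationError, DataError, NumericError
from .model import ModelConfig, extractor_gradient, init_model, make_batch

_SEED_MOD = 2**31
DEGENERATE_NORM = 1e-12


@dataclass(frozen=True)
class PGMConfig:
    n_restarts: int = 10
    restart_mode: str = "same_init"  # "same_init" | "random_init"
    base_seed: int = 0
    batch_size: int = 32

    def __post_init__(self):
        if self.n_restarts < 1 or self.batch_size < 1:
            raise ConfigurationError("n_restarts and batch_size must be positive")
        if self.restart_mode not in ("same_init", "random_init"):
            raise ConfigurationError(f"unknown restart_mode {self.restart_mode!r}")


def config_hash(model_config: ModelConfig, pgm_config: PGMConfig) -> str:
    """Digest identifying the model/restart configuration two principal
    gradients must share in order to be comparable."""
    payload = {
        "model": {k: v for k, v in asdict(model_config).items() if k != "predictor_out"},
        "pgm": asdict(pgm_config),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PrincipalGradient:
    """Expected extractor gradient of one dataset with provenance."""

    vector: np.ndarray
    n_restarts: int
    config_hash: str
    dataset_name: str
    task_type: str

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.all(np.isfinite(self.vector)):
            raise NumericError(f"non-finite principal gradient for {self.dataset_name}")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.vector))

    def save(self, prefix) -> None:
        """Persist as flat array + JSON sidecar."""
        np.save(f"{prefix}.npy", self.vector)
        sidecar = {
            "n_restarts": self.n_restarts,
            "config_hash": self.config_hash,
            "dataset_name": self.dataset_name,
            "task_type": self.task_type,
            "norm": self.norm,
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, prefix) -> "PrincipalGradient":
        vector = np.load(f"{prefix}.npy")
        with open(f"{prefix}.json") as fh:
            sidecar = json.load(fh)
        return cls(vector, sidecar["n_restarts"], sidecar["config_hash"],
                   sidecar["dataset_name"], sidecar["task_type"])


def _shuffle_seed(base_seed: int, restart: int, dataset_name: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [base_seed % _SEED_MOD, restart, zlib.crc32(dataset_name.encode())]
    )


def _restart_mean(graphs, labels, observed, task, cfg, pgm_config, k, name):
    """One restart: (re)initialize, shuffle, unweighted mean of per-batch
    extractor gradients.  No parameter is ever updated."""
    if pgm_config.restart_mode == "same_init":
        init_seed = pgm_config.base_seed
    else:
        init_seed = pgm_config.base_seed + k
    state = init_model(replace(cfg, init_seed=init_seed))
    rng = np.random.default_rng(_shuffle_seed(pgm_config.base_seed, k, name))
    order = rng.permutation(len(graphs))
    batch_grads = []
    for start in range(0, len(order), pgm_config.batch_size):
        idx = order[start:start + pgm_config.batch_size]
        if not observed[idx].any():
            continue  # batch unusable: no observed label cells
        batch = make_batch([graphs[i] for i in idx], labels[idx], observed[idx])
        batch_grads.append(extractor_gradient(state, batch, task))
    if not batch_grads:
        raise DataError(
            f"restart {k} of {name!r} produced no usable batches (no observed labels)"
        )
    return np.mean(batch_grads, axis=0)


def restart_gradient(records: list[MoleculeRecord], task: TaskSpec,
                     model_config: ModelConfig, pgm_config: PGMConfig,
                     restart: int, dataset_name: str | None = None) -> np.ndarray:
    """Mean extractor gradient of one specific restart (diagnostic API).

    The principal gradient equals the mean of these vectors over
    ``restart = 0 .. n_restarts-1``.
    """
    name = dataset_name or task.name
    cfg = replace(model_config, predictor_out=task.n_subtasks)
    graphs = [featurize(r) for r in records]
    labels = np.stack([r.labels for r in records])
    observed = np.stack([r.observed for r in records])
    return _restart_mean(graphs, labels, observed, task, cfg, pgm_config, restart, name)


class PrincipalGradientEstimator(BaseEstimator):
    """Estimator computing a dataset's principal gradient.

    Parameters
    ----------
    model_config : ModelConfig
        Shared encoder configuration.  Must be identical across every
        dataset whose gradients will be compared.
    pgm_config : PGMConfig
        Restart scheme: number of update-free passes, initialization mode,
        base seed and batch size.

    Attributes
    ----------
    gradient_ : PrincipalGradient
        The expected extractor gradient after :meth:`fit`.
    restart_norms_ : list of float
        Euclidean norm of each restart's mean gradient (logged diagnostics).
    """

    def __init__(self, model_config: ModelConfig | None = None,
                 pgm_config: PGMConfig | None = None):
        self.model_config = model_config
        self.pgm_config = pgm_config

    def fit(self, records: list[MoleculeRecord], task: TaskSpec, dataset_name: str | None = None):
        model_config = self.model_config or ModelConfig()
        pgm_config = self.pgm_config or PGMConfig()
        if not records:
            raise DataError("cannot compute a principal gradient on an empty dataset")
        name = dataset_name or task.name
        cfg = replace(model_config, predictor_out=task.n_subtasks)
        graphs = [featurize(r) for r in records]
        labels = np.stack([r.labels for r in records])
        observed = np.stack([r.observed for r in records])
        restart_means = [
            _restart_mean(graphs, labels, observed, task, cfg, pgm_config, k, name)
            for k in range(pgm_config.n_restarts)
        ]
        norms = [float(np.linalg.norm(g)) for g in restart_means]
        vector = np.mean(restart_means, axis=0)
        self.restart_norms_ = norms
        self.gradient_ = PrincipalGradient(
            vector=vector,
            n_restarts=pgm_config.n_restarts,
            config_hash=config_hash(model_config, pgm_config),
            dataset_name=name,
            task_type=task.task_type,
        )
        return self


def principal_gradient(records, task: TaskSpec, model_config: ModelConfig,
                       pgm_config: PGMConfig, dataset_name: str | None = None) -> PrincipalGradient:
    """Expected extractor gradient over update-free restarts (functional API)."""
    est = PrincipalGradientEstimator(model_config, pgm_config)
    return est.fit(records, task, dataset_name=dataset_name).gradient_


def pgm_distance(pg_s: PrincipalGradient, pg_t: PrincipalGradient) -> float:
    """Normalized distance between two principal gradients (smaller = more
    related): ``||t - s|| / (||s|| * ||t||)``.  Symmetric in its arguments."""
    if pg_s.config_hash != pg_t.config_hash:
        raise ComparabilityError(
            f"principal gradients of {pg_s.dataset_name!r} and {pg_t.dataset_name!r} "
            "were computed under different configurations"
        )
    if pg_s.vector.shape != pg_t.vector.shape:
        raise ComparabilityError("principal gradient vectors have different lengths")
    ns, nt = pg_s.norm, pg_t.norm
    if ns < DEGENERATE_NORM or nt < DEGENERATE_NORM:
        raise NumericError(
            "degenerate (near-zero) principal gradient; the model setup is broken"
        )
    return float(np.linalg.norm(pg_t.vector - pg_s.vector) / (ns * nt))


@dataclass
class TransferabilityMap:
    """Square matrix of pairwise PGM distances over named datasets."""

    names: list[str]
    distances: np.ndarray
    task_types: dict[str, str] = field(default_factory=dict)
    mixed_task_types: bool = False

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=np.float64)
        n = len(self.names)
        if self.distances.shape != (n, n):
            raise ConfigurationError("distance matrix shape does not match names")

    def distance(self, a: str, b: str) -> float:
        return float(self.distances[self.names.index(a), self.names.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.names, columns=self.names)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "TransferabilityMap":
        df = pd.read_csv(path, index_col=0)
        return cls(names=list(df.index), distances=df.to_numpy())

    def plot_heatmap(self, path) -> None:
        """Render the map as a heatmap image (small distance = warm color)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(self.names),) * 2)
        im = ax.imshow(self.distances, cmap="coolwarm_r")
        ax.set_xticks(range(len(self.names)), self.names, rotation=90)
        ax.set_yticks(range(len(self.names)), self.names)
        for i in range(len(self.names)):
            for j in range(len(self.names)):
                ax.text(j, i, f"{self.distances[i, j]:.2g}", ha="center",
                        va="center", fontsize=7)
        fig.colorbar(im, ax=ax, label="PGM distance")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


class TransferabilityMapper(BaseEstimator):
    """Estimator building the pairwise PGM-distance map of several datasets.

    ``fit`` takes a list of ``(name, records, task_spec)`` triples; each
    principal gradient is computed once, then all pairwise distances.

    Attributes
    ----------
    gradients_ : dict mapping name -> PrincipalGradient
    map_ : TransferabilityMap
    """

    def __init__(self, model_config: ModelConfig | None = None,
                 pgm_config: PGMConfig | None = None):
        self.model_config = model_config
        self.pgm_config = pgm_config

    def fit(self, datasets: list[tuple[str, list[MoleculeRecord], TaskSpec]]):
        if len(datasets) < 2:
            raise ConfigurationError("a transferability map needs at least 2 datasets")
        names = [name for name, _, _ in datasets]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"dataset names must be unique, got {names}")
        self.gradients_ = {}
        for name, records, task in datasets:
            try:
                self.gradients_[name] = principal_gradient(
                    records, task, self.model_config or ModelConfig(),
                    self.pgm_config or PGMConfig(), dataset_name=name)
            except (DataError, NumericError) as exc:
                raise type(exc)(f"dataset {name!r}: {exc}") from exc
        n = len(names)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    d = pgm_distance(self.gradients_[names[i]], self.gradients_[names[j]])
                except NumericError as exc:
                    raise NumericError(f"pair ({names[i]}, {names[j]}): {exc}") from exc
                dist[i, j] = dist[j, i] = d
        task_types = {name: task.task_type for name, _, task in datasets}
        self.map_ = TransferabilityMap(
            names=names,
            distances=dist,
            task_types=task_types,
            mixed_task_types=len(set(task_types.values())) > 1,
        )
        return self


def build_map(datasets, model_config: ModelConfig, pgm_config: PGMConfig) -> TransferabilityMap:
    """Pairwise PGM-distance map over ``(name, records, task)`` triples."""
    return TransferabilityMapper(model_config, pgm_config).fit(datasets).map_


def rank_sources(tmap: TransferabilityMap, target: str) -> list[tuple[str, float]]:
    """Source datasets ranked by ascending PGM distance to *target*.

    Ties are broken alphabetically by dataset name.
    """
    if target not in tmap.names:
        raise ConfigurationError(f"target {target!r} not in map {tmap.names}")
    row = tmap.distances[tmap.names.index(target)]
    pairs = [(name, float(d)) for name, d in zip(tmap.names, row) if name != target]
    return sorted(pairs, key=lambda p: (p[1], p[0]))
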