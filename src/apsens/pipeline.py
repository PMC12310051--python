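"""Configuration, evaluation caching and the end-to-end pipeline runner.

The pipeline composes the stages sample -> evaluate (with cache) ->
biomarkers -> Sobol indices + bootstrap CIs -> grand ranking -> reduced-
model hierarchy, and serialises every artifact (tidy CSV tables, minimal-
set JSON, a manifest).  Long campaigns are resumable: the evaluation cache
doubles as a checkpoint, keyed by the model id, the scaling vector and the
protocol/tolerance configuration, so a rerun with a warm cache performs
zero model evaluations and reproduces outputs bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .biomarkers import (
    AP_BIOMARKER_NAMES, CA_BIOMARKER_NAMES,
    extract_ap_biomarkers, extract_ca_biomarkers,
    NoAPError, DegenerateTransientError,
)
from .gsa import ParameterRanges, SobolSensitivity, TABLE4_RANGES
from .reduction import ReductionStudy
from .shannon import (
    CURRENT_NAMES, PacingProtocol, ScalingVector, SimulationError,
    SolverSettings, simulate_train,
)
from .validation import SurrogateAPModel

__all__ = ["RunConfig", "EvaluationCache", "ShannonEvaluator",
           "SurrogateEvaluator", "PipelineResult", "run_pipeline"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Complete description of a sensitivity campaign.

    Defaults are the standard setup: stimulus 9.5 A/F for 5 ms, BCL 500 ms,
    trains of 1000 beats with the final beat analysed, the one-at-a-time
    normal-response parameter box, base sample size M = 8192 with
    second-order blocks, 1000 bootstrap replicates, equal biomarker
    weights, and L = 2000 reduction sample points.  Scale M, L and the
    train length down for desk-scale runs.
    """

    # pacing protocol
    stim_amplitude: float = 9.5
    stim_duration: float = 5.0
    bcl: float = 500.0
    n_beats: int = 1000
    record_last: int = 1
    # parameter box
    ranges: dict = field(default_factory=lambda: {
        "p" + n: list(TABLE4_RANGES["p" + n]) for n in CURRENT_NAMES
    })
    # sensitivity estimation
    M: int = 8192
    second_order: bool = True
    bootstrap_reps: int = 1000
    weights: list | None = None
    # reduction
    L: int = 2000
    levels: list | None = None
    minimal_threshold: float = 0.9
    # randomness
    seed: int = 0
    # solver
    rtol: float = 1e-6
    atol_gating: float = 1e-6
    atol_conc: float = 1e-8
    # biomarker selection and failure policy
    use_ap_biomarkers: bool = True
    use_ca_biomarkers: bool = False
    failure_mode: str = "strict"          # "strict" | "tolerant"
    # io
    cache_path: str | None = None
    out_dir: str = "results"

    def __post_init__(self):
        if self.failure_mode not in ("strict", "tolerant"):
            raise ValueError("failure_mode must be 'strict' or 'tolerant'")
        if not (self.use_ap_biomarkers or self.use_ca_biomarkers):
            raise ValueError("at least one biomarker family must be selected")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        s = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_yaml(cls, path_or_str) -> "RunConfig":
        if os.path.exists(str(path_or_str)):
            with open(path_or_str) as fh:
                d = yaml.safe_load(fh)
        else:
            d = yaml.safe_load(path_or_str)
        return cls.from_dict(d)

    # -- derived objects -----------------------------------------------------

    def protocol(self) -> PacingProtocol:
        return PacingProtocol(
            stim_amplitude=self.stim_amplitude,
            stim_duration=self.stim_duration,
            bcl=self.bcl, n_beats=self.n_beats, record_last=self.record_last,
        )

    def solver(self) -> SolverSettings:
        return SolverSettings(rtol=self.rtol, atol_gating=self.atol_gating,
                              atol_conc=self.atol_conc)

    def parameter_ranges(self) -> ParameterRanges:
        return ParameterRanges.from_dict(
            {k: tuple(v) for k, v in self.ranges.items()}
        )

    def biomarker_names(self) -> list:
        names = []
        if self.use_ap_biomarkers:
            names += list(AP_BIOMARKER_NAMES)
        if self.use_ca_biomarkers:
            names += list(CA_BIOMARKER_NAMES)
        return names

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# evaluation cache
# ---------------------------------------------------------------------------


class EvaluationCache:
    """Append-only JSON-lines cache of biomarker evaluations.

    Keyed by (model id, scaling-vector hash, protocol, tolerances); a cache
    hit returns exactly the stored vector, so warm reruns are bitwise
    identical and perform zero model evaluations.
    """

    def __init__(self, path=None):
        self.path = path
        self._data: dict[str, list] = {}
        self.hits = 0
        self.misses = 0
        if path is not None and os.path.exists(path):
            with open(path) as fh:
                for line in fh:
                    if line.strip():
                        rec = json.loads(line)
                        self._data[rec["key"]] = rec["y"]

    @staticmethod
    def key_for(model_id: str, p, context: tuple) -> str:
        payload = (model_id, tuple(np.asarray(p, float).tolist()), context)
        return hashlib.sha256(repr(payload).encode()).hexdigest()

    def get(self, key):
        v = self._data.get(key)
        if v is not None:
            self.hits += 1
        return v

    def put(self, key, y) -> None:
        self.misses += 1
        y = list(map(float, y))
        self._data[key] = y
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps({"key": key, "y": y}) + "\n")

    def __len__(self):
        return len(self._data)


# ---------------------------------------------------------------------------
# evaluators (parameter rows -> biomarker matrix)
# ---------------------------------------------------------------------------


class ShannonEvaluator:
    """Maps scaling-factor rows to final-beat biomarker vectors by paced
    simulation of the Shannon model.

    In tolerant mode, failed evaluations (solver failure or no AP) yield
    NaN rows and are counted; in strict mode they raise with the offending
    sample attached.
    """

    model_id = "shannon"

    def __init__(self, config: RunConfig, cache: EvaluationCache | None = None):
        self.config = config
        self.cache = cache if cache is not None else EvaluationCache(config.cache_path)
        self.protocol = config.protocol()
        self.solver = config.solver()
        self.n_failed = 0
        self._context = (
            self.protocol.stim_amplitude, self.protocol.stim_duration,
            self.protocol.bcl, self.protocol.n_beats,
            self.solver.rtol, self.solver.atol_gating, self.solver.atol_conc,
            tuple(self.config.biomarker_names()),
        )

    def evaluate_one(self, p_row) -> list:
        tr = simulate_train(np.asarray(p_row, float), self.protocol, self.solver)
        y = []
        if self.config.use_ap_biomarkers:
            y += list(extract_ap_biomarkers(tr, -1).to_array())
        if self.config.use_ca_biomarkers:
            y += list(extract_ca_biomarkers(tr, -1).to_array())
        return y

    def __call__(self, rows) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows, float))
        K = len(self.config.biomarker_names())
        out = np.empty((rows.shape[0], K))
        for i, row in enumerate(rows):
            key = EvaluationCache.key_for(self.model_id, row, self._context)
            hit = self.cache.get(key)
            if hit is not None:
                out[i] = hit
                continue
            try:
                y = self.evaluate_one(row)
            except (SimulationError, NoAPError, DegenerateTransientError) as exc:
                if self.config.failure_mode == "strict":
                    raise SimulationError(
                        f"evaluation failed in strict mode for sample {row.tolist()}: {exc}",
                        p=row,
                    ) from exc
                self.n_failed += 1
                out[i] = np.nan
                continue
            self.cache.put(key, y)
            out[i] = y
        return out


class SurrogateEvaluator:
    """Biomarkers of the fast AP surrogate, via closed forms (default) or
    via waveform generation + extraction (``mode='waveform'``)."""

    model_id = "surrogate"

    def __init__(self, config: RunConfig, surrogate: SurrogateAPModel | None = None,
                 mode: str = "closed_form"):
        if mode not in ("closed_form", "waveform"):
            raise ValueError("mode must be 'closed_form' or 'waveform'")
        self.config = config
        self.surrogate = surrogate or SurrogateAPModel(bcl=config.bcl)
        self.mode = mode
        self.n_failed = 0

    def __call__(self, rows) -> np.ndarray:
        rows = np.atleast_2d(np.asarray(rows, float))
        if self.mode == "closed_form":
            return self.surrogate.biomarker_matrix(
                rows, include_ca=self.config.use_ca_biomarkers
            ) if self.config.use_ap_biomarkers else np.asarray([
                self.surrogate.closed_form_ca(q).to_array() for q in rows
            ])
        out = []
        for q in rows:
            tr = self.surrogate.evaluate(q)
            y = []
            if self.config.use_ap_biomarkers:
                y += list(extract_ap_biomarkers(tr, 0).to_array())
            if self.config.use_ca_biomarkers:
                y += list(extract_ca_biomarkers(tr, 0).to_array())
            out.append(y)
        return np.asarray(out)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    config: RunConfig
    sobol: object                 # SobolResults
    ranking: object               # GrandRanking
    reduction: object             # ReductionReport
    manifest: dict
    artifacts: dict               # name -> path (when written)


def _atomic_write(path, text):
    tmp = str(path) + ".tmp"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def run_pipeline(config: RunConfig, model: str = "shannon",
                 write: bool = True) -> PipelineResult:
    """Run the full campaign described by ``config``.

    ``model`` selects the evaluator: ``"shannon"`` (paced ODE model over
    the fifteen scaling factors) or ``"surrogate"`` (fast waveform
    surrogate over its six pseudo-parameters; its own box is used).
    All randomness derives from ``config.seed``.
    """
    if model == "shannon":
        evaluator = ShannonEvaluator(config)
        ranges = config.parameter_ranges()
    elif model == "surrogate":
        evaluator = SurrogateEvaluator(config)
        ranges = evaluator.surrogate.ranges
    else:
        raise ValueError("model must be 'shannon' or 'surrogate'")

    names = config.biomarker_names()
    sens = SobolSensitivity(
        evaluator, ranges, M=config.M, second_order=config.second_order,
        output_names=names,
        failure_policy="strict" if config.failure_mode == "strict" else "drop",
        bootstrap_reps=config.bootstrap_reps,
    )
    sobol = sens.fit(seed=config.seed)
    ranking = sobol.grand_ranking(weights=config.weights)

    study = ReductionStudy(
        evaluator, ranges, ranking, levels=config.levels, L=config.L,
        seed=config.seed + 1, output_names=names,
    )
    report = study.fit(minimal_threshold=config.minimal_threshold,
                       ST_matrix=sobol.total_matrix())

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "model": model,
        "seed": config.seed,
        "n_evaluations_design": sobol.sample.n_evaluations,
        "n_failed": sobol.n_failed + getattr(evaluator, "n_failed", 0),
        "cache": {
            "hits": getattr(getattr(evaluator, "cache", None), "hits", None),
            "misses": getattr(getattr(evaluator, "cache", None), "misses", None),
        },
    }

    artifacts = {}
    if write:
        os.makedirs(config.out_dir, exist_ok=True)
        def path(name):
            return os.path.join(config.out_dir, name)
        _atomic_write(path("indices.csv"), sobol.summary().to_csv(index=False))
        if config.second_order:
            _atomic_write(path("second_order.csv"),
                          sobol.second_order_table().to_csv(index=False))
        _atomic_write(path("ranking.csv"), ranking.to_frame().to_csv(index=False))
        _atomic_write(path("reduction.csv"), report.levels.to_csv(index=False))
        if report.minimal is not None:
            _atomic_write(path("minimal_sets.json"), report.minimal_sets_json())
        _atomic_write(path("manifest.json"), json.dumps(manifest, indent=1))
        artifacts = {
            "indices": path("indices.csv"),
            "ranking": path("ranking.csv"),
            "reduction": path("reduction.csv"),
            "manifest": path("manifest.json"),
        }
        if config.second_order:
            artifacts["second_order"] = path("second_order.csv")
        if report.minimal is not None:
            artifacts["minimal_sets"] = path("minimal_sets.json")

    return PipelineResult(config=config, sobol=sobol, ranking=ranking,
                          reduction=report, manifest=manifest,
                          artifacts=artifacts)
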