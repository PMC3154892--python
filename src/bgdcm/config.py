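"""Run configuration: every numeric threshold of the analysis surfaced as a
named field with its default, loadable from a YAML document and logged in
full at the start of each run."""

from __future__ import annotations

import logging
import sys
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

logger = logging.getLogger("bgdcm")


@dataclass
class RunConfig:
    grid_start_hz: float = 10.0
    grid_stop_hz: float = 35.0
    grid_step_hz: float = 1.0
    ar_order: int = 8
    sampling_rate_hz: float = 250.0
    max_iterations: int = 64
    free_energy_tol: float = 1e-2      # convergence: change in F below this
    lam_burnin: int = 8
    fd_step: float = 1e-3
    beta_band_hz: tuple = (16.0, 18.0)
    gamma_band_hz: tuple = (59.0, 61.0)
    prob_threshold: float = 0.9999     # posterior difference criterion
    n_comparisons: int = 9             # Bonferroni family size
    between_sd: float = 0.1
    n_segments: int = 60
    seed: int = 0

    def grid(self):
        import numpy as np

        return np.arange(self.grid_start_hz, self.grid_stop_hz + self.grid_step_hz,
                         self.grid_step_hz)

    def validate(self) -> None:
        if self.grid_step_hz <= 0 or self.grid_stop_hz <= self.grid_start_hz:
            raise ValueError("invalid frequency grid")
        if self.ar_order < 1:
            raise ValueError("ar_order must be >= 1")
        if not (0.5 < self.prob_threshold < 1.0):
            raise ValueError("prob_threshold must be in (0.5, 1)")
        if self.free_energy_tol <= 0:
            raise ValueError("free_energy_tol must be positive")
        if self.between_sd < 0 or self.n_segments < 1:
            raise ValueError("invalid cohort settings")

    @classmethod
    def load(cls, path: str | Path | None) -> "RunConfig":
        cfg = cls()
        if path is not None:
            with open(path) as fh:
                doc = yaml.safe_load(fh) or {}
            known = set(asdict(cfg))
            unknown = set(doc) - known
            if unknown:
                raise ValueError(f"unknown config keys: {sorted(unknown)}")
            for k, v in doc.items():
                setattr(cfg, k, tuple(v) if isinstance(v, list) else v)
        cfg.validate()
        return cfg

    def log(self) -> None:
        logger.info("resolved config: %s", asdict(self))


def setup_logging(logfile: str | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(level=level, handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
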