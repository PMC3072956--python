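"""Run configuration: one flat key-value YAML file, CLI flags override.

Schema (all keys optional; defaults shown):

    lambda: auto        # trade-off, 'auto' or a float >= 0
    mu: 0.5             # entropy vs non-uniformity weight in C(mu, lambda)
    seed: 0             # master seed for all stochastic stages
    sparseness: 0.8     # Hoyer sparseness target for S columns
    tau: 0.1            # relative active-TF detection threshold
    restrict_to_w: true # limit active TFs to motif-supported ones
    cutoff: 0.7         # per-TF normalized strength cutoff for modules
    fdr: 1.0            # FDR threshold for modules
    preference: median  # AP preference ('median' or float)
    damping: 0.9
    standardize: center # expression pre-treatment: none|center|zscore
    tfa_profile: exemplar  # exemplar|mean
    enrichment_mode: sampling  # sampling|exact
    enrichment_draws: 10000
    pwm_cutoff: 0.75    # promoter-scan score cutoff (fraction of range)
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

__all__ = ["MsdConfig", "load_config"]


@dataclass
class MsdConfig:
    lam: float | str = "auto"
    mu: float = 0.5
    seed: int = 0
    sparseness: float = 0.8
    tau: float = 0.1
    restrict_to_w: bool = True
    cutoff: float = 0.7
    fdr: float = 1.0
    preference: float | str = "median"
    damping: float = 0.9
    standardize: str = "center"
    tfa_profile: str = "exemplar"
    enrichment_mode: str = "sampling"
    enrichment_draws: int = 10_000
    pwm_cutoff: float = 0.75

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lambda"] = d.pop("lam")
        return d


_KEY_ALIASES = {"lambda": "lam"}


def load_config(path=None, **overrides) -> MsdConfig:
    """Load a YAML config file and apply keyword overrides (CLI flags).

    Overrides with value None are ignored so absent CLI flags fall through
    to file values and defaults. The effective seed is logged.
    """
    data: dict = {}
    if path is not None:
        with open(Path(path)) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping")
        data.update(loaded)
    for k, v in overrides.items():
        if v is not None:
            data[k] = v
    known = set(MsdConfig.__dataclass_fields__)
    kwargs = {}
    for k, v in data.items():
        key = _KEY_ALIASES.get(k, k)
        if key not in known:
            raise ValueError(f"unknown config key: {k}")
        kwargs[key] = v
    cfg = MsdConfig(**kwargs)
    if cfg.lam != "auto":
        cfg.lam = float(cfg.lam)
    logger.info("config: seed=%d lambda=%s mu=%g", cfg.seed, cfg.lam, cfg.mu)
    return cfg
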