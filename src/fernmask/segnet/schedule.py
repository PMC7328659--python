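"""One-cycle learning-rate policy.

A single cycle over the whole run: cosine warmup from ``lr_max /
div_factor`` up to ``lr_max`` during the first ``warmup_fraction`` of
steps, then cosine annealing down to ``lr_max / final_div_factor``.  The
trace is continuous with exactly one interior maximum at the warmup end.
"""

from __future__ import annotations

import math

from .config import TrainConfig


def one_cycle_lr(step: int, total_steps: int, cfg: TrainConfig) -> float:
    """Learning rate at ``step`` (0-based) of a ``total_steps``-step run."""
    if total_steps < 1:
        raise ValueError("total_steps must be >= 1")
    if not 0 <= step < total_steps:
        raise ValueError(f"step {step} out of range [0, {total_steps})")
    lr_start = cfg.lr_max / cfg.div_factor
    lr_final = cfg.lr_max / cfg.final_div_factor
    warmup_steps = cfg.warmup_fraction * (total_steps - 1)
    if total_steps == 1:
        return cfg.lr_max
    if step <= warmup_steps:
        u = step / warmup_steps if warmup_steps > 0 else 1.0
        return lr_start + (cfg.lr_max - lr_start) * 0.5 * (1.0 - math.cos(math.pi * u))
    u = (step - warmup_steps) / (total_steps - 1 - warmup_steps)
    return lr_final + (cfg.lr_max - lr_final) * 0.5 * (1.0 + math.cos(math.pi * u))
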