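"""Resource accounting for pretraining: A100-day equivalents and machine-hour
cost.

Compute is measured in "A100 days": one day on a reference datacentre GPU.
Other GPUs convert through a relative-throughput factor (for example, a
consumer card rated 0.82 of the reference: 8 hours on it is
(8/24) * 0.82 = 0.27 A100 days). Cost assumes an 8-GPU machine at a flat
hourly price (default $30), so cost = (A100 days / 8) * 24 h * price.

A hook accepts a user-supplied kg-CO2-per-kWh factor for emissions estimates;
no emission factors are shipped.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ComputeSpec",
    "CostSpec",
    "a100_day_equivalent",
    "stage_sum",
    "training_cost",
    "co2_equivalent",
    "format_cost",
]


@dataclass(frozen=True)
class ComputeSpec:
    gpu_hours: float
    n_gpus: int = 1
    relative_throughput: float = 1.0  # vs the reference GPU

    def __post_init__(self):
        if self.gpu_hours < 0 or self.n_gpus < 0 or self.relative_throughput < 0:
            raise ValueError("compute spec fields must be nonnegative")


@dataclass(frozen=True)
class CostSpec:
    hourly_machine_price: float = 30.0
    gpus_per_machine: int = 8

    def __post_init__(self):
        if self.hourly_machine_price <= 0 or self.gpus_per_machine <= 0:
            raise ValueError("cost spec fields must be positive")


def a100_day_equivalent(spec: ComputeSpec) -> float:
    """(gpu_hours / 24) * n_gpus * relative_throughput, rounded to 2 decimals
    for reporting."""
    return round(spec.gpu_hours / 24.0 * spec.n_gpus * spec.relative_throughput, 2)


def stage_sum(stage_days) -> float:
    """Total A100 days across pipeline stages."""
    days = list(stage_days)
    if any(d < 0 for d in days):
        raise ValueError("stage days must be nonnegative")
    return float(sum(days))


def training_cost(a100_days: float, cost: CostSpec | None = None) -> float:
    """Price of the compute: days of an N-GPU machine times its hourly price,
    i.e. (a100_days / gpus_per_machine) * 24 * hourly_machine_price."""
    cost = cost or CostSpec()
    if a100_days < 0:
        raise ValueError("a100_days must be nonnegative")
    return a100_days / cost.gpus_per_machine * 24.0 * cost.hourly_machine_price


def co2_equivalent(a100_days: float, kwh_per_a100_day: float,
                   kg_co2_per_kwh: float) -> float:
    """Emissions from a user-supplied grid factor; nothing is shipped."""
    if min(a100_days, kwh_per_a100_day, kg_co2_per_kwh) < 0:
        raise ValueError("arguments must be nonnegative")
    return a100_days * kwh_per_a100_day * kg_co2_per_kwh


def format_cost(dollars: float) -> str:
    """Whole dollars above $100, cents below (the precision the worked
    examples are reported at)."""
    if dollars > 100:
        return f"${round(dollars):,}"
    return f"${dollars:.2f}"
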