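"""Mechanistic simulator of division-coupled methylation erosion.

Each cell division, maintenance methylation fails at a CpG with
context-dependent probability r, and unmethylated sites gain methylation
de novo with probability g, so the population-mean methylation evolves as

    beta' = beta * (1 - r) + g * (1 - beta * (1 - r))

This contraction has a unique fixed point beta* = g / (1 - (1-r)(1-g)):
erosion proceeds geometrically (ratio (1-r)(1-g) per division) toward a
low hypomethylated equilibrium where de novo gains offset further loss —
the plateau seen in immortalized cultures that keep dividing long past
replicative senescence.

Per-CpG failure rates are modulated by replication timing (later-
replicating CpGs have less time for replication-coupled maintenance,
multiplier 1 + kappa*(0.917 - WA)/0.917), and transcription is
protective (multiplier 1 - e*expression). A small per-day loss term u
models maintenance failure during unscheduled (repair-associated) DNA
synthesis under oxidative stress, which continues even in growth-
arrested cells.

Cultures are simulated passage by passage. Each passage specifies a
growth ratio (viable yield over inoculum) and elapsed days; the implied
population doublings follow PD = 3.32*(log10 yield - log10 inoculum),
applied as integer division steps plus one rate-scaled fractional step.
Observed betas are drawn around the true beta from a Beta distribution
parameterized by mean and precision nu (mean-preserving and bounded to
(0,1), unlike additive Gaussian noise); the exact betas are returned in
a truth table.

A companion generator plants CpGs with controlled flanks, inter-CpG
spacings straddling the 35-bp solo boundary, and domain intervals into a
synthetic contig, providing planted truth for the annotator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSequence, IntervalSet
from .meth_io import PD_LOG_CONSTANT, cumulative_pds

# Per-division (maintenance failure r, de novo gain g) by context class.
# Chosen once to reproduce the qualitative rate ordering
# soloWCGW_PMD < social_PMD < nonPMD (slopes), a slight net gain at social
# non-PMD CpGs, and an erosion plateau ~40 PDs past a ~60-PD senescence.
DEFAULT_RATES = {
    "soloWCGW_PMD": (0.030, 0.003),
    "social_PMD": (0.012, 0.003),
    "solo_nonPMD": (0.002, 0.0008),
    "social_nonPMD": (0.0002, 0.002),
}

# Starting (pre-culture, zygote-like) mean beta per class
DEFAULT_BETA0 = {
    "soloWCGW_PMD": 0.88,
    "social_PMD": 0.85,
    "solo_nonPMD": 0.82,
    "social_nonPMD": 0.80,
}

CLASS_FLANK = {
    "soloWCGW_PMD": "WCGW",
    "social_PMD": "SCGS",
    "solo_nonPMD": "WCGW",
    "social_nonPMD": "SCGS",
}
CLASS_SOLO = {
    "soloWCGW_PMD": True,
    "social_PMD": False,
    "solo_nonPMD": True,
    "social_nonPMD": False,
}
CLASS_DOMAIN = {
    "soloWCGW_PMD": "commonPMD",
    "social_PMD": "commonPMD",
    "solo_nonPMD": "neither",
    "social_nonPMD": "neither",
}


def step_methylation(beta, r_eff, g):
    """One division: maintenance failure then compensatory de novo gain."""
    beta = np.asarray(beta, dtype=float)
    r_eff = np.asarray(r_eff, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any((beta < 0) | (beta > 1)):
        raise ValueError("beta must lie in [0, 1]")
    if np.any((r_eff < 0) | (r_eff >= 1)):
        raise ValueError("maintenance failure rate must lie in [0, 1)")
    if np.any((g < 0) | (g >= 1)):
        raise ValueError("de novo gain rate must lie in [0, 1)")
    kept = beta * (1.0 - r_eff)
    out = kept + g * (1.0 - kept)
    return float(out) if out.ndim == 0 else out


def equilibrium_beta(r, g):
    """Fixed point of :func:`step_methylation`: beta* = g / (1-(1-r)(1-g))."""
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any((r < 0) | (r >= 1)) or np.any((g < 0) | (g >= 1)):
        raise ValueError("rates must lie in [0, 1)")
    if np.any(r + g == 0):
        raise ValueError("r = g = 0 has no unique equilibrium")
    out = g / (1.0 - (1.0 - r) * (1.0 - g))
    return float(out) if out.ndim == 0 else out


@dataclass
class ContextRates:
    """Per-context (maintenance failure, de novo gain) rates per division."""

    rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATES)
    )

    def __post_init__(self) -> None:
        for cls, (r, g) in self.rates.items():
            if not (0 <= r < 1 and 0 <= g < 1):
                raise ValueError(f"class {cls!r}: rates must lie in [0, 1)")


@dataclass
class SimulationConfig:
    """World parameters for a culture simulation.

    kappa couples the failure rate to replication timing; expression
    protection scales it down at gene-linked CpGs; uds_rate is the
    per-day loss during unscheduled DNA synthesis (ambient oxygen);
    noise_precision is the Beta-noise precision (None = noiseless).
    """

    rates: ContextRates = field(default_factory=ContextRates)
    kappa: float = 0.5
    expression_protection: float = 0.5
    uds_rate: float = 1e-4
    noise_precision: float | None = 100.0
    probes_per_class: int = 150
    expressed_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not 0 <= self.expression_protection <= 1:
            raise ValueError("expression protection must lie in [0, 1]")
        if self.uds_rate < 0:
            raise ValueError("uds_rate must be >= 0")
        if self.noise_precision is not None and not (
            self.noise_precision > 0
        ):
            raise ValueError("noise precision must be > 0 (or None)")


@dataclass
class Lineage:
    """One cultured lineage: an in-vivo starting offset plus a passage
    schedule of (growth_ratio, days) tuples. growth_ratio = viable yield /
    inoculum; ratio 1 with days > 0 models growth arrest (PDs frozen,
    time advancing)."""

    name: str
    offset_pd: float = 0.0
    schedule: list[tuple[float, float]] = field(default_factory=list)
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.offset_pd < 0:
            raise ValueError("offset PD must be >= 0")
        for ratio, days in self.schedule:
            if ratio <= 0:
                raise ValueError(
                    f"lineage {self.name!r}: growth ratio must be positive"
                )
            if days < 0:
                raise ValueError(f"lineage {self.name!r}: days must be >= 0")


@dataclass
class CultureScenario:
    lineages: list[Lineage]
    inoculum: float = 1e6


def _probe_panel(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Probe-level truth: class, starting beta, WA, expression, effective rates."""
    rows = []
    for cls, (r, g) in config.rates.rates.items():
        n = config.probes_per_class
        beta0 = np.clip(
            DEFAULT_BETA0.get(cls, 0.8) + rng.normal(0, 0.03, n), 0.05, 0.98
        )
        late = CLASS_DOMAIN.get(cls, "neither") == "commonPMD"
        wa = rng.uniform(0.10, 0.45, n) if late else rng.uniform(0.55, 0.90, n)
        expressed = rng.random(n) < config.expressed_fraction
        expression = np.where(expressed, rng.uniform(0.2, 1.0, n), 0.0)
        timing_mult = 1.0 + config.kappa * (0.917 - wa) / 0.917
        expr_mult = 1.0 - config.expression_protection * expression
        r_eff = np.clip(r * timing_mult * expr_mult, 0.0, 0.999)
        for i in range(n):
            rows.append(
                {
                    "probe_id": f"{cls}_{i:04d}",
                    "class": cls,
                    "flank_class": CLASS_FLANK.get(cls, "intermediate"),
                    "solo": CLASS_SOLO.get(cls, True),
                    "domain": CLASS_DOMAIN.get(cls, "neither"),
                    "in_cgi": False,
                    "beta0": beta0[i],
                    "wa": wa[i],
                    "expression": expression[i],
                    "r": r,
                    "g": g,
                    "r_eff": r_eff[i],
                }
            )
    return pd.DataFrame(rows).set_index("probe_id")


def _advance(beta, r_eff, g, divisions: float):
    """Apply ``divisions`` doubling steps: integer steps plus one
    rate-scaled partial step for the fractional remainder."""
    whole = int(math.floor(divisions))
    frac = divisions - whole
    for _ in range(whole):
        beta = step_methylation(beta, r_eff, g)
    if frac > 0:
        beta = step_methylation(beta, r_eff * frac, g * frac)
    return beta


def _observe(beta, nu, rng: np.random.Generator):
    if nu is None or np.isinf(nu):
        return np.asarray(beta, dtype=float).copy()
    m = np.clip(np.asarray(beta, dtype=float), 1e-6, 1 - 1e-6)
    return rng.beta(m * nu, (1 - m) * nu)


def simulate_culture(
    config: SimulationConfig, scenario: CultureScenario
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate serially passaged cultures measured at every passage.

    Returns (beta matrix probes x samples, sample sheet with cum_pd, truth)
    where truth holds the noiseless beta matrix, the probe panel (classes,
    per-probe effective rates, WA, expression) and per-sample true total
    divisions (offset + culture PDs) and elapsed days.

    The sample sheet's yield/inoculum/inoculum_pd columns are constructed
    so that chaining the PD equation reproduces the scheduled PDs exactly.
    """
    rng = np.random.default_rng(config.seed)
    panel = _probe_panel(config, rng)
    r_eff = panel["r_eff"].to_numpy()
    g = panel["g"].to_numpy()

    sheet_rows, obs_cols, true_cols, truth_samples = [], {}, {}, []
    for lin in scenario.lineages:
        beta = panel["beta0"].to_numpy().copy()
        beta = _advance(beta, r_eff, g, lin.offset_pd)  # in-vivo history
        cum_pd, days_total = 0.0, 0.0

        def _record(passage_idx, yield_ratio):
            sid = f"{lin.name}_p{passage_idx:02d}"
            obs_cols[sid] = _observe(beta, config.noise_precision, rng)
            true_cols[sid] = beta.copy()
            sheet_rows.append(
                {
                    "sample_id": sid,
                    "lineage": lin.name,
                    "passage": passage_idx,
                    "cell_yield": scenario.inoculum * yield_ratio,
                    "inoculum": scenario.inoculum,
                    "inoculum_pd": 0.0,
                    "days": days_total,
                    **lin.condition,
                }
            )
            truth_samples.append(
                {
                    "sample_id": sid,
                    "lineage": lin.name,
                    "true_total_pd": lin.offset_pd + cum_pd,
                    "culture_pd": cum_pd,
                    "days": days_total,
                }
            )

        _record(0, 1.0)
        for idx, (ratio, days) in enumerate(lin.schedule, start=1):
            delta_pd = PD_LOG_CONSTANT * math.log10(ratio)
            if delta_pd < 0:
                raise ValueError(
                    f"lineage {lin.name!r} passage {idx}: shrinking culture"
                )
            beta = _advance(beta, r_eff, g, delta_pd)
            if config.uds_rate > 0 and days > 0:
                uds = min(config.uds_rate * days, 0.999)
                beta = step_methylation(beta, uds, 0.0)
            cum_pd += delta_pd
            days_total += days
            _record(idx, ratio)

    beta_obs = pd.DataFrame(obs_cols, index=panel.index)
    beta_true = pd.DataFrame(true_cols, index=panel.index)
    sheet = pd.DataFrame(sheet_rows)
    sheet["cum_pd"] = cumulative_pds(sheet)
    truth = {
        "beta_true": beta_true,
        "probes": panel,
        "samples": pd.DataFrame(truth_samples).set_index("sample_id"),
    }
    return beta_obs, sheet, truth


# --- canonical scenarios -------------------------------------------------

def standard_scenario(
    n_lineages: int = 7,
    n_passages: int = 26,
    growth_ratio: float = 4.0,
    days_per_passage: float = 7.0,
    offsets: list[float] | None = None,
) -> CultureScenario:
    """Serial culture of several primary lineages with distinct in-vivo
    replicative histories, passaged through ~52 culture PDs each
    (growth ratio 4 per passage = 2 PDs)."""
    if offsets is None:
        offsets = [round(5 + 45 * i / max(n_lineages - 1, 1), 1) for i in range(n_lineages)]
    if len(offsets) != n_lineages:
        raise ValueError("need one starting offset per lineage")
    return CultureScenario(
        lineages=[
            Lineage(
                name=f"line{i}",
                offset_pd=offsets[i],
                schedule=[(growth_ratio, days_per_passage)] * n_passages,
            )
            for i in range(n_lineages)
        ]
    )


def immortalized_scenario(
    n_passages: int = 100, growth_ratio: float = 4.0, days_per_passage: float = 4.0
) -> CultureScenario:
    """A telomerase-immortalized lineage cultured far past the normal
    replicative lifespan (~200 PDs), long enough to reach the erosion
    plateau."""
    return CultureScenario(
        lineages=[
            Lineage(
                name="immortalized",
                offset_pd=20.0,
                schedule=[(growth_ratio, days_per_passage)] * n_passages,
            )
        ]
    )


def serum_scenario(
    serum_levels: tuple[float, ...] = (15.0, 5.0, 1.0, 0.5),
    divisions_per_day: tuple[float, ...] = (0.50, 0.35, 0.22, 0.15),
    total_days: float = 140.0,
    days_per_passage: float = 7.0,
) -> CultureScenario:
    """Parallel cultures of one cell type slowed to different division
    rates by serum restriction: equal elapsed time, unequal PDs."""
    if len(serum_levels) != len(divisions_per_day):
        raise ValueError("one division rate per serum level")
    n_passages = int(total_days / days_per_passage)
    lineages = []
    for serum, rate in zip(serum_levels, divisions_per_day):
        ratio = 2.0 ** (rate * days_per_passage)
        lineages.append(
            Lineage(
                name=f"serum{serum:g}",
                offset_pd=10.0,
                schedule=[(ratio, days_per_passage)] * n_passages,
                condition={"serum": serum},
            )
        )
    return CultureScenario(lineages=lineages)


def arrest_scenario(
    pre_passages: int = 3,
    arrest_days: tuple[float, ...] = (18.0, 7.0),
    control_passages: int = 6,
    growth_ratio: float = 4.0,
    days_per_passage: float = 4.0,
) -> CultureScenario:
    """A replication-blocked (crosslinker-arrested) culture and its
    freely proliferating control: after shared early passages the treated
    lineage stops dividing (growth ratio 1) while days keep advancing."""
    shared = [(growth_ratio, days_per_passage)] * pre_passages
    treated = shared + [(1.0, d) for d in arrest_days]
    control = shared + [(growth_ratio, days_per_passage)] * (
        control_passages - pre_passages
    )
    return CultureScenario(
        lineages=[
            Lineage("treated", 15.0, treated, {"treatment": "arrest"}),
            Lineage("control", 15.0, control, {"treatment": "vehicle"}),
        ]
    )


# --- synthetic genome ----------------------------------------------------

def simulate_genome(
    n_per_class: dict[str, int],
    contig_length: int | None = None,
    seed: int = 0,
    contig_name: str = "sim1",
    solo_gap_choices: tuple[int, ...] = (35, 36, 45, 60),
    social_gap_choices: tuple[int, ...] = (10, 20, 28, 34),
) -> tuple[GenomeSequence, pd.DataFrame, dict[str, IntervalSet]]:
    """Plant CpGs of the four canonical context classes into a synthetic
    contig, with spacings straddling the 35-bp solo boundary.

    Filler bases are A/T only, so no accidental CpG can arise and every
    planted flank is controlled. Returns (genome, truth table, interval
    sets) where the truth table records each planted CpG's intended
    flank class, solo status, nearest-CpG distance class, and domain.
    Raises on infeasible requests (odd social counts below 2, or a layout
    exceeding ``contig_length``).
    """
    rng = np.random.default_rng(seed)
    unknown = set(n_per_class) - set(CLASS_FLANK)
    if unknown:
        raise ValueError(f"unknown context classes: {sorted(unknown)}")

    def flank(cls):
        pool = "AT" if CLASS_FLANK[cls] == "WCGW" else "CG"
        return pool[rng.integers(len(pool))]

    # a unit = one solo CpG or a social run of 2-3 CpGs
    units: list[tuple[str, int]] = []  # (class, run length)
    for cls, n in n_per_class.items():
        if n == 0:
            continue
        if CLASS_SOLO[cls]:
            units.extend([(cls, 1)] * n)
        else:
            if n < 2:
                raise ValueError(
                    f"class {cls!r}: social CpGs come in runs of >=2, got {n}"
                )
            runs = [2] * (n // 2)
            if n % 2:
                runs[-1] = 3
            units.extend((cls, run) for run in runs)
    # PMD units first so a single PMD interval covers them
    units.sort(key=lambda u: CLASS_DOMAIN[u[0]] != "commonPMD")

    chars: list[str] = []
    truth_rows = []
    pmd_end = 0
    last_domain = None

    def filler(n):
        chars.extend("AT"[rng.integers(2)] for _ in range(n))

    filler(int(rng.integers(40, 60)))
    for cls, run in units:
        domain = CLASS_DOMAIN[cls]
        if last_domain == "commonPMD" and domain != "commonPMD":
            pmd_end = len(chars) + 2  # past the previous unit
            filler(45)
        positions = []
        for j in range(run):
            if j > 0:
                gap = int(rng.choice(social_gap_choices))
                filler(gap - 2 - 2)  # gap is C-to-C start distance
            left = flank(cls)
            right = flank(cls)
            chars.append(left)
            positions.append(len(chars))
            chars.extend("CG")
            chars.append(right)
        for j, pos in enumerate(positions):
            if run == 1:
                nearest_cls = "solo"
            else:
                nearest_cls = "social"
            truth_rows.append(
                {
                    "contig": contig_name,
                    "pos": pos,
                    "flank_class": CLASS_FLANK[cls],
                    "solo": CLASS_SOLO[cls],
                    "class": cls,
                    "domain": domain,
                    "in_cgi": False,
                    "spacing": nearest_cls,
                }
            )
        last_domain = domain
        # start-to-start distance to the next unit's first CpG equals the
        # drawn gap exactly: CG (2) + right flank (1) + filler + left flank (1)
        filler(int(rng.choice(solo_gap_choices)) - 4)
    if last_domain == "commonPMD":
        pmd_end = len(chars)
    filler(int(rng.integers(40, 60)))

    # gap-based filler between units: ensure solo separation >= 35 by
    # construction (solo_gap_choices min 35, applied start-to-start)
    sequence = "".join(chars)
    if contig_length is not None:
        if len(sequence) > contig_length:
            raise ValueError(
                f"layout needs {len(sequence)} bp but contig_length="
                f"{contig_length}; infeasible packing"
            )
        sequence += "A" * (contig_length - len(sequence))
    genome = GenomeSequence(contig_name, sequence)
    truth = pd.DataFrame(truth_rows).sort_values("pos").reset_index(drop=True)
    interval_sets = {
        "commonPMD": IntervalSet(
            "commonPMD",
            [(contig_name, 0, pmd_end)] if pmd_end > 0 else [],
        )
    }
    return genome, truth, interval_sets
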