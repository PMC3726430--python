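"""Synthetic expression and productivity data emulating the 4-line study design.

The generator produces the same shape of data the analysis consumes: a
log2-scale expression matrix over 4 inbred lines x 2 depression levels x 3
sublines plus 3 outbred controls (27 samples), a matching sample sheet, a
ground-truth table of planted effects, and a replicate-level productivity
table.  Null probes are Gaussian on the log2 scale with the study's per-group
within-line variances (0.028 controls / 0.044 least / 0.086 most depressed)
and an optional block-exchangeable correlation between probes, which makes the
correlation-preserving randomization test non-trivial.  Planted probes receive
an additive shift in whole sublines of one (line, level) cell — the causal
picture of a fixed, line-specific genetic alteration.

The default planted configuration mirrors the headline candidate pattern: 14
down-regulated probes in most-depressed cells, 6/3/2/3 across lines b/c/d/a,
each line's probes sharing a correlation block (common regulation), with 2
affected sublines each (the two-outlier case).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import study
from .data_model import ExpressionMatrix, ProductivityTable, SampleSheet

_LEVEL_SHORT = {"most_depressed": "most", "least_depressed": "least"}


@dataclass(frozen=True)
class PlantedEffect:
    """A line-specific expression alteration planted into the null matrix.

    ``delta`` is the additive log2 shift applied to the first ``n_affected``
    sublines of the target (line, level) cell; its sign must match
    ``direction`` (negative for down-regulation).
    """

    probe_index: int
    line: str
    level: str = "most_depressed"
    direction: str = "down"
    delta: float = -2.0
    n_affected: int = 2


def default_planted(block_size: int = 50) -> tuple[PlantedEffect, ...]:
    """The 14-probe headline-like configuration (6/3/2/3 in lines b/c/d/a)."""
    effects = []
    for block, (line, count) in enumerate([("b", 6), ("c", 3), ("d", 2),
                                           ("a", 3)]):
        for k in range(count):
            effects.append(PlantedEffect(probe_index=block * block_size + k,
                                         line=line))
    return tuple(effects)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study's printed conditions."""

    n_probes: int = 9000
    lines: tuple[str, ...] = study.LINES
    levels: tuple[str, ...] = study.LEVELS
    sublines_per_cell: int = study.SUBLINES_PER_CELL
    n_controls: int = study.N_CONTROLS
    baseline_mean: float = 8.0
    var_control: float = study.WITHIN_LINE_VARIANCES["control"]
    var_least: float = study.WITHIN_LINE_VARIANCES["least_depressed"]
    var_most: float = study.WITHIN_LINE_VARIANCES["most_depressed"]
    block_size: int = 50
    block_rho: float = 0.3
    planted: tuple[PlantedEffect, ...] = field(
        default_factory=default_planted)
    w_o: float = study.W_O
    w_i: float = study.W_I
    n_sublines_per_line: int = 25
    n_replicates_per_subline: int = 3
    n_control_vials: int = 70
    subline_sd: float = 12.0
    productivity_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        for name in ("var_control", "var_least", "var_most"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not abs(self.block_rho) < 1:
            raise ValueError("|block_rho| must be < 1")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        planted = tuple(
            p if isinstance(p, PlantedEffect) else PlantedEffect(**p)
            for p in self.planted
        )
        for p in planted:
            if not 0 <= p.probe_index < self.n_probes:
                raise ValueError(
                    f"planted probe index {p.probe_index} out of range "
                    f"[0, {self.n_probes})"
                )
            if p.line not in self.lines or p.level not in self.levels:
                raise ValueError(
                    f"planted effect references unknown cell "
                    f"({p.line!r}, {p.level!r})"
                )
            if p.delta == 0:
                raise ValueError("planted delta must be non-zero")
            if (p.direction == "down") != (p.delta < 0):
                raise ValueError(
                    f"planted delta sign ({p.delta}) inconsistent with "
                    f"direction {p.direction!r}"
                )
            if not 1 <= p.n_affected <= self.sublines_per_cell:
                raise ValueError("n_affected must be in [1, sublines_per_cell]")
        if len({p.probe_index for p in planted}) != len(planted):
            raise ValueError("duplicate planted probe indices")
        self.planted = planted

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted"] = [dataclasses.asdict(p) for p in self.planted]
        d["lines"] = list(self.lines)
        d["levels"] = list(self.levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "planted" in d:
            d["planted"] = tuple(
                p if isinstance(p, PlantedEffect) else PlantedEffect(**p)
                for p in d["planted"]
            )
        for key in ("lines", "levels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from YAML or JSON."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Sample layout
# ---------------------------------------------------------------------------


def design_sheet(config: SimulationConfig) -> SampleSheet:
    """Sample sheet for the configured design (inbred cells first, controls last)."""
    rows = []
    for line in config.lines:
        for level in config.levels:
            for k in range(1, config.sublines_per_cell + 1):
                sid = f"{line}_{_LEVEL_SHORT.get(level, level)}_{k}"
                rows.append((sid, "inbred", line, level, k))
    for k in range(1, config.n_controls + 1):
        rows.append((f"control_{k}", "control", "none", "none", k))
    return SampleSheet(pd.DataFrame(rows, columns=["sample_id", "role", "line",
                                                   "level", "subline_index"]))


def _sample_sds(config: SimulationConfig, sheet: SampleSheet) -> np.ndarray:
    var_by_group = {
        "most_depressed": config.var_most,
        "least_depressed": config.var_least,
        None: config.var_control,
    }
    sds = []
    for _, row in sheet.table.iterrows():
        level = None if row["role"] == "control" else row["level"]
        sds.append(np.sqrt(var_by_group[level]))
    return np.asarray(sds)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def simulate_expression(config: SimulationConfig
                        ) -> tuple[ExpressionMatrix, SampleSheet, pd.DataFrame]:
    """Draw an expression matrix, its sample sheet, and the planted-effect truth.

    Deterministic given ``config.seed``.  Noise for probe p, sample s is
    ``sd_s * (sqrt(rho) * z[block(p), s] + sqrt(1-rho) * eps[p, s])`` with iid
    standard normals ``z`` and ``eps``, giving exchangeable correlation
    ``block_rho`` inside each block of ``block_size`` probes and the target
    within-group variance ``sd_s**2`` for every probe.
    """
    sheet = design_sheet(config)
    n_samples = len(sheet.sample_ids)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 11]))

    n_blocks = -(-config.n_probes // config.block_size)
    z = rng.standard_normal((n_blocks, n_samples))
    eps = rng.standard_normal((config.n_probes, n_samples))
    block_of = np.arange(config.n_probes) // config.block_size
    rho = config.block_rho
    noise = np.sqrt(rho) * z[block_of] + np.sqrt(1.0 - rho) * eps

    sds = _sample_sds(config, sheet)
    values = config.baseline_mean + noise * sds[None, :]

    probe_ids = [f"probe_{i:05d}" for i in range(config.n_probes)]
    sample_ids = sheet.sample_ids
    col_index = {s: j for j, s in enumerate(sample_ids)}

    truth_rows = []
    for p in config.planted:
        short = _LEVEL_SHORT.get(p.level, p.level)
        affected = [f"{p.line}_{short}_{k}" for k in range(1, p.n_affected + 1)]
        cols = [col_index[s] for s in affected]
        values[p.probe_index, cols] += p.delta
        truth_rows.append({
            "probe_id": probe_ids[p.probe_index],
            "line": p.line,
            "level": p.level,
            "direction": p.direction,
            "delta": p.delta,
            "affected_samples": ";".join(affected),
        })

    matrix = ExpressionMatrix(pd.DataFrame(values, index=probe_ids,
                                           columns=sample_ids))
    truth = pd.DataFrame(truth_rows, columns=["probe_id", "line", "level",
                                              "direction", "delta",
                                              "affected_samples"])
    return matrix, sheet, truth


# ---------------------------------------------------------------------------
# Productivity
# ---------------------------------------------------------------------------


def simulate_productivity(config: SimulationConfig) -> ProductivityTable:
    """Replicate-level pupa counts: inbred sublines plus control vials.

    Per-subline means are Normal(w_i, subline_sd) truncated at 0.5 so the
    implied per-subline depression rates span roughly the printed 0.64-1.4
    range; replicate vials scatter with coefficient of variation
    ``productivity_cv``.  Control vials are Normal(w_o, cv * w_o), matching
    the printed control standard error over 70 vials.  Deterministic given
    ``config.seed``; drawn from a stream independent of the expression draw.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 23]))
    cv = config.productivity_cv
    rows = []
    for line in config.lines:
        means = np.clip(
            rng.normal(config.w_i, config.subline_sd,
                       size=config.n_sublines_per_line),
            0.5, None)
        for s, mu in enumerate(means, start=1):
            reps = np.clip(
                rng.normal(mu, cv * mu, size=config.n_replicates_per_subline),
                0.0, None)
            for r, v in enumerate(reps, start=1):
                rows.append((line, s, r, float(v)))
    control = np.clip(
        rng.normal(config.w_o, cv * config.w_o, size=config.n_control_vials),
        0.0, None)
    for r, v in enumerate(control, start=1):
        rows.append(("control", 0, r, float(v)))
    return ProductivityTable(pd.DataFrame(
        rows, columns=["line", "subline_id", "replicate_id",
                       "pupae_per_female"]))


def null_calibration_config(seed: int = 0, n_probes: int = 9000,
                            **overrides) -> SimulationConfig:
    """A config generating data under the randomization test's null hypothesis.

    The code-relabeling test assumes the (line, level) codes of the inbred
    sublines are exchangeable.  The study-condition defaults are NOT null in
    that sense: a higher within-group variance in most-depressed sublines is
    itself a level-associated expression signal, and the test (correctly)
    detects it.  For type-I calibration the inbred groups therefore share one
    within-line variance — the pooled mean of the two study values,
    (0.044 + 0.086) / 2 = 0.065 — and no effects are planted.
    """
    inbred_var = (study.WITHIN_LINE_VARIANCES["least_depressed"]
                  + study.WITHIN_LINE_VARIANCES["most_depressed"]) / 2.0
    kwargs = dict(n_probes=n_probes, planted=(), var_most=inbred_var,
                  var_least=inbred_var, seed=seed)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def write_simulation(config: SimulationConfig, outdir: str | Path,
                     header_lines: Sequence[str] = ()) -> dict[str, Path]:
    """Emit matrix/sheet/truth/productivity TSVs plus the config as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, sheet, truth = simulate_expression(config)
    prod = simulate_productivity(config)
    paths = {
        "matrix": outdir / "expression_matrix.tsv",
        "sheet": outdir / "sample_sheet.tsv",
        "truth": outdir / "truth_table.tsv",
        "productivity": outdir / "productivity.tsv",
        "config": outdir / "simulation_config.json",
    }
    matrix.to_tsv(paths["matrix"], header_lines=header_lines)
    sheet.to_tsv(paths["sheet"], header_lines=header_lines)
    from .data_model import write_table

    write_table(truth, paths["truth"], header_lines=header_lines)
    prod.to_tsv(paths["productivity"], header_lines=header_lines)
    paths["config"].write_text(json.dumps(config.to_dict(), indent=1) + "\n")
    return paths
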