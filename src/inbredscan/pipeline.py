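"""End-to-end orchestration: simulate/load -> scan -> SL-LD -> randomize -> report.

``run_pipeline`` executes every desk-scale stage of the analysis on either
user-supplied TSVs or a fresh simulation, and writes a reproducible report
bundle: outlier calls, SL-LD calls, the alpha ladder with randomization
p-values, a depression summary, per-cluster correlation reports, the candidate
dendrogram with bootstrap support, and a human-readable summary.  Given the
same config and seed the bundle is byte-identical; every table carries the
package version, seed, and a hash of the serialized config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .data_model import (read_expression_matrix, read_productivity_table,
                         read_sample_sheet, write_table)
from .depression import summarize_depression
from .grubbs import sequential_outlier_scan
from .postanalysis import bootstrap_support, correlation_with_without
from .simulate import SimulationConfig, simulate_expression, simulate_productivity
from .slld import alpha_ladder, classify_slld

logger = logging.getLogger("inbredscan")


@dataclass
class RunConfig:
    """Every pipeline knob; defaults mirror the documented design decisions."""

    # inputs: paths to TSVs, or None to simulate
    matrix_path: str | None = None
    sheet_path: str | None = None
    productivity_path: str | None = None
    outdir: str = "results"
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    alphas: tuple[float, ...] = (0.10, 0.05, 0.025, 0.01)
    candidate_alpha: float = 0.05
    n_outliers: int = 2
    mode: str = "at_least"           # probes with >= n calls stay eligible
    directions: tuple[str, ...] = ("up", "down")
    max_outliers: int = 3
    n_replicates: int = 10_000
    sidedness: str = "one"           # one-sided Grubbs per direction
    include_controls: bool = False   # controls excluded from the scan
    most_comparison: str = "total"   # conservative "+"-style comparison
    add_one: bool = False
    f_coefficient: float = 0.7
    cut_height: float = 0.5
    n_boot: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        for key in ("alphas", "directions"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and not isinstance(d["sim"], SimulationConfig):
            d["sim"] = SimulationConfig.from_dict(d["sim"])
        for key in ("alphas", "directions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle to ``config.outdir``.

    Returns a dict of the in-memory results (``ladder``, ``slld_calls``,
    ``randomization``, ``depression``, ``clusters``, ``correlation_reports``)
    plus the output paths.  Any stage failure aborts with a stage-named error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    meta = [f"inbredscan {__version__}", f"seed={config.seed}",
            f"config_hash={config.config_hash()}"]
    results: dict = {"outdir": outdir}
    try:
        # ---- stage: inputs ------------------------------------------------
        stage = "load-inputs"
        if config.matrix_path:
            matrix = read_expression_matrix(config.matrix_path)
            sheet = read_sample_sheet(config.sheet_path, matrix=matrix,
                                      cross_check=True)
            logger.info("%s: loaded matrix %s and sheet %s", stage,
                        config.matrix_path, config.sheet_path)
        else:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            matrix, sheet, truth = simulate_expression(sim)
            write_table(truth, outdir / "truth_table.tsv", header_lines=meta)
            logger.info("%s: simulated %d probes x %d samples (seed=%d)",
                        stage, *matrix.shape, config.seed)
        if config.productivity_path:
            productivity = read_productivity_table(config.productivity_path)
        elif not config.matrix_path:
            productivity = simulate_productivity(
                dataclasses.replace(config.sim, seed=config.seed))
        else:
            productivity = None

        # ---- stage: scan at candidate alpha -------------------------------
        stage = "grubbs-scan"
        all_calls = []
        calls_by_direction = {}
        for direction in config.directions:
            calls = sequential_outlier_scan(
                matrix, sheet=sheet, alpha=config.candidate_alpha,
                max_outliers=config.max_outliers, direction=direction,
                sidedness=config.sidedness,
                include_controls=config.include_controls)
            calls_by_direction[direction] = calls
            all_calls.append(calls)
            logger.info("%s: direction=%s alpha=%g -> %d calls", stage,
                        direction, config.candidate_alpha, len(calls))
        outlier_calls = _concat(all_calls)
        write_table(outlier_calls, outdir / "outlier_calls.tsv",
                    header_lines=meta)

        # ---- stage: SL-LD classification ----------------------------------
        stage = "slld-classify"
        slld_frames = []
        for direction, calls in calls_by_direction.items():
            slld_frames.append(classify_slld(calls, sheet,
                                             n_outliers=config.n_outliers,
                                             mode=config.mode))
        slld_calls = _concat(slld_frames)
        write_table(slld_calls, outdir / "slld_calls.tsv", header_lines=meta)
        results["slld_calls"] = slld_calls
        logger.info("%s: %d SL-LD probes at alpha=%g", stage, len(slld_calls),
                    config.candidate_alpha)

        # ---- stage: alpha ladder + randomization --------------------------
        stage = "alpha-ladder"
        ladder = alpha_ladder(
            matrix, sheet, alphas=config.alphas,
            n_outliers=config.n_outliers, directions=config.directions,
            n_replicates=config.n_replicates, seed=config.seed,
            max_outliers=config.max_outliers, mode=config.mode,
            sidedness=config.sidedness,
            include_controls=config.include_controls,
            most_comparison=config.most_comparison)
        write_table(ladder, outdir / "ladder.tsv", header_lines=meta)
        results["ladder"] = ladder
        rand_payload = {
            "meta": meta,
            "n_replicates": config.n_replicates,
            "seed": config.seed,
            "most_comparison": config.most_comparison,
            "rows": json.loads(ladder.to_json(orient="records")),
        }
        (outdir / "randomization.json").write_text(
            json.dumps(rand_payload, indent=1) + "\n")
        logger.info("%s: %d (alpha, direction) cells, %d replicates each",
                    stage, len(ladder), config.n_replicates)

        # ---- stage: depression summary ------------------------------------
        stage = "depression"
        if productivity is not None:
            summary = summarize_depression(productivity,
                                           f=config.f_coefficient)
            (outdir / "depression.json").write_text(
                json.dumps({"meta": meta, **summary.to_dict()}, indent=1)
                + "\n")
            results["depression"] = summary
            logger.info("%s: W_O=%.2f W_I=%.2f IDR=%.4f", stage, summary.w_o,
                        summary.w_i, summary.overall_idr)

        # ---- stage: postanalysis on down/most candidates ------------------
        stage = "postanalysis"
        candidates = slld_calls[
            (slld_calls["direction"] == "down")
            & (slld_calls["level"] == "most_depressed")]
        results["candidates"] = candidates
        if len(candidates) >= 2:
            genes = list(candidates["probe_id"])
            tree = bootstrap_support(matrix, genes, n_boot=config.n_boot,
                                     seed=config.seed,
                                     cut_height=config.cut_height)
            results["clusters"] = tree
            (outdir / "dendrogram.newick").write_text(tree.newick + "\n")
            write_table(tree.merge_table(), outdir / "merge_table.tsv",
                        header_lines=meta)
            reports = {}
            by_sample = dict(zip(candidates["probe_id"],
                                 candidates["outlier_samples"]))
            for cid, members in tree.labels.groupby(tree.labels):
                cluster_genes = list(members.index)
                if len(cluster_genes) < 2:
                    continue
                removed = sorted({s for g in cluster_genes
                                  for s in by_sample[g].split(";")})
                rep = correlation_with_without(matrix, cluster_genes,
                                               removed_samples=removed)
                reports[int(cid)] = rep
            results["correlation_reports"] = reports
            (outdir / "correlation_reports.json").write_text(json.dumps(
                {"meta": meta,
                 "clusters": {str(k): v.to_dict() for k, v in reports.items()}},
                indent=1) + "\n")
            logger.info("%s: %d candidate genes in %d clusters", stage,
                        len(genes), tree.labels.nunique())
        else:
            logger.info("%s: <2 down/most candidates; skipped clustering",
                        stage)

        # ---- stage: report ------------------------------------------------
        stage = "report"
        (outdir / "config.json").write_text(
            json.dumps(config.to_dict(), indent=1, sort_keys=True) + "\n")
        (outdir / "summary.txt").write_text(_render_summary(config, results))
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return results


def _concat(frames: list[pd.DataFrame]) -> pd.DataFrame:
    non_empty = [f for f in frames if not f.empty]
    if not non_empty:
        return frames[0]
    return pd.concat(non_empty, ignore_index=True)


def _render_summary(config: RunConfig, results: dict) -> str:
    lines = [
        f"inbredscan {__version__}  seed={config.seed}  "
        f"config_hash={config.config_hash()}",
        "",
        "Alpha ladder (observed vs randomization-expected SL-LD counts):",
    ]
    ladder = results["ladder"]
    for _, row in ladder.iterrows():
        flag = " *" if row["p_total"] < 0.05 else ""
        lines.append(
            f"  alpha={row['alpha']:<6g} {row['direction']:<5} "
            f"observed={int(row['observed_total'])} "
            f"(most={int(row['observed_most'])}, "
            f"least={int(row['observed_least'])}) "
            f"expected={row['expected_mean']:.2f} "
            f"p_total={row['p_total']:.4f}{flag}"
        )
    if "depression" in results:
        s = results["depression"]
        lines += ["", f"Productivity: W_O={s.w_o:.2f} W_I={s.w_i:.2f} "
                      f"F={s.f:g} overall IDR={s.overall_idr:.4f} per unit F"]
    cand = results.get("candidates")
    if cand is not None:
        lines += ["", f"Down-regulated SL-LD candidates in most-depressed "
                      f"cells at alpha={config.candidate_alpha:g}: "
                      f"{len(cand)}"]
        if "clusters" in results:
            tree = results["clusters"]
            sizes = tree.labels.value_counts().sort_index()
            lines.append("Cluster sizes: "
                         + ", ".join(str(int(v)) for v in sizes))
        for cid, rep in sorted(results.get("correlation_reports",
                                           {}).items()):
            lines.append(
                f"  cluster {cid}: mean r={rep.mean_r_full:.3f} "
                f"(n={rep.n_full}), r'={rep.mean_r_reduced:.3f} "
                f"(n={rep.n_reduced}, removed "
                f"{len(rep.removed_samples)} sublines)"
            )
    return "\n".join(lines) + "\n"
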