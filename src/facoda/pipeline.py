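"""End-to-end pipeline: generate or ingest a cohort, filter, describe, fit
all compositional and substitution models, and emit change matrices.

Outputs mirror the analysis's published tables: cohort summary (table1),
compositional geometric means + variation matrix (table2), compositional
regressions (table3), substitution models (table4), change matrices (table5),
plus tidy quintile-bar and ternary-coordinate data, a subject-selection tally
and a run manifest.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, reference as ref
from .change import change_matrix
from .composition import compositional_geometric_mean, variation_matrix
from .descriptives import amalgamate, quintile_clr_bars, summary_table, ternary_coords
from .filters import FilterConfig, apply_exclusions
from .regression import fit_compositional
from .simulate import GeneratorConfig, generate
from .substitution import fit_substitution

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _run_stage(name: str, fn):
    try:
        return fn()
    except Exception as e:  # noqa: BLE001 - reported with stage context
        raise PipelineError(name, e) from e


@dataclass
class PipelineConfig:
    """Run configuration: generate a cohort or ingest an existing CSV."""

    mode: str = "generate"  # "generate" | "ingest"
    seed: int = 0
    n: int = 5485
    cohort_path: str | None = None  # ingest mode
    delta: float = 4.0
    outcomes: tuple[str, ...] = tuple(ref.FIRST_PIVOT_COEFS)
    generator: GeneratorConfig | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    render_plots: bool = False

    def resolved_generator(self) -> GeneratorConfig:
        if self.generator is not None:
            return self.generator
        return GeneratorConfig(n=self.n, seed=self.seed)


def _hash_config(config: PipelineConfig) -> str:
    gen = config.resolved_generator().to_manifest() if config.mode == "generate" else None
    blob = json.dumps(
        {
            "mode": config.mode, "seed": config.seed, "n": config.n,
            "delta": config.delta, "outcomes": list(config.outcomes),
            "generator": gen,
            "filters": {
                "eer_low": config.filters.eer_low,
                "eer_high": config.filters.eer_high,
                "ldl_cut": config.filters.ldl_cut,
            },
        },
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_cohort(config: PipelineConfig) -> pd.DataFrame:
    if config.mode == "generate":
        return generate(config.resolved_generator())
    if config.mode == "ingest":
        if not config.cohort_path:
            raise ValueError("ingest mode needs cohort_path")
        return pd.read_csv(config.cohort_path)
    raise ValueError(f"unknown mode {config.mode!r}")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; write artifacts under ``outdir``; return manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "package_version": __version__,
        "config_hash": _hash_config(config),
        "seed": config.seed,
        "stages": {},
    }
    parts = list(ref.FA_PARTS)
    part_cols = [f"{p}_pct" for p in parts]

    cohort = _run_stage("cohort", lambda: _load_cohort(config))
    manifest["stages"]["cohort"] = {"rows": len(cohort)}
    cohort.to_csv(outdir / "cohort.csv", index=False)

    def do_filter():
        kept, tally = apply_exclusions(cohort, config.filters)
        if kept.empty:
            raise ValueError("no subjects retained after exclusions")
        return kept, tally

    kept, tally = _run_stage("filter", do_filter)
    manifest["stages"]["filter"] = {"rows": len(kept), "excluded": tally}
    (outdir / "exclusions.json").write_text(json.dumps(tally, indent=2))

    def do_descriptives():
        summary_table(kept).to_csv(outdir / "table1_summary.csv", index=False)
        X = kept[part_cols].to_numpy()
        gm = compositional_geometric_mean(X)
        T = variation_matrix(X)
        t2 = pd.DataFrame(T, index=parts, columns=parts)
        t2.insert(0, "geometric_mean", gm)
        t2.to_csv(outdir / "table2_variation.csv")
        bars = []
        for outcome in config.outcomes:
            b = quintile_clr_bars(kept, outcome, parts)
            b = b.reset_index().melt(id_vars="quintile", var_name="part",
                                     value_name="clr_height")
            b.insert(0, "outcome", outcome)
            bars.append(b)
        pd.concat(bars).to_csv(outdir / "fig2_quintile_bars.csv", index=False)
        tern = []
        for merge in (("omega6", "omega3"), ("MUFA", "omega3"),
                      ("MUFA", "omega6"), ("SFA", "MUFA")):
            sub, labels = amalgamate(X, parts, merge)
            xy = ternary_coords(sub)
            df = pd.DataFrame(xy, columns=["x", "y"])
            df.insert(0, "triangle", "/".join(labels))
            tern.append(df)
        pd.concat(tern).to_csv(outdir / "fig1_ternary_coords.csv", index=False)
        return gm, T

    gm, _T = _run_stage("descriptives", do_descriptives)

    def do_coda():
        fits = {o: fit_compositional(kept, o) for o in config.outcomes}
        pd.DataFrame([r.to_row() for r in fits.values()]).to_csv(
            outdir / "table3_compositional.csv", index=False
        )
        full = {
            o: {
                "clr_coefs": r.clr_coefs.to_dict(),
                "rsquared": r.rsquared_unadjusted,
                "f_pvalue": r.f_pvalue_unadjusted,
                "n": r.nobs,
            }
            for o, r in fits.items()
        }
        (outdir / "table3_compositional.json").write_text(json.dumps(full, indent=2))
        return fits

    coda_fits = _run_stage("coda_fits", do_coda)

    def do_substitution():
        rows = []
        for outcome in config.outcomes:
            for target in parts:
                rows.append(fit_substitution(kept, outcome, target).to_row())
        pd.DataFrame(rows).to_csv(outdir / "table4_substitution.csv", index=False)

    _run_stage("substitution_fits", do_substitution)

    def do_changes():
        frames = []
        for outcome, res in coda_fits.items():
            kind = "ratio" if res.model.log_outcome else "difference"
            cm = change_matrix(res.clr_coefs.to_numpy(), gm, parts,
                               delta=config.delta, kind=kind, outcome=outcome)
            f = cm.to_frame().reset_index(names="to_part")
            f.insert(0, "kind", kind)
            f.insert(0, "outcome", outcome)
            frames.append(f)
        pd.concat(frames).to_csv(outdir / "table5_change_matrices.csv", index=False)

    _run_stage("change_matrices", do_changes)

    if config.render_plots:
        def do_plots():
            from .plots import plot_quintile_bars, plot_ternary
            bars = quintile_clr_bars(kept, config.outcomes[0], parts)
            plot_quintile_bars(bars, config.outcomes[0], outdir / "fig2_example.svg")
            sub, labels = amalgamate(kept[part_cols].to_numpy(), parts,
                                     ("omega6", "omega3"))
            plot_ternary(sub, labels, outdir / "fig1_example.svg")

        _run_stage("plots", do_plots)

    manifest["wall_time_s"] = round(time.time() - t0, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
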