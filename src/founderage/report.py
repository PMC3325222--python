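"""End-to-end analysis orchestration and report bundles.

:func:`run_analysis` wires the full pipeline — conserved-region detection,
founder-allele rule, per-marker moment estimators, across-marker averaging,
optional demography block — and writes a report bundle under an output
directory: a per-marker TSV mirroring the usual founder-dating table layout
(marker, founder allele, distance, per-estimator generations, average row
with CI), a conserved-region report, a demography report and a JSON summary
carrying unrounded values alongside the display strings, plus a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping, Sequence

import pandas as pd

from . import __version__
from .age_estimators import (
    MarkerAgeInput,
    TmrcaSummary,
    average_tmrca,
    bergman_g,
    informativeness_filter,
    labuda_correct,
    risch_g,
)
from .demography import CensusPair, growth_rate, hwe_allele_freq, prevalence
from .genetic_map import MarkerDef
from .haplotypes import (
    ChromosomePanel,
    allele_frequency,
    conserved_region,
    founder_allele,
)

__all__ = ["AnalysisResult", "run_analysis", "average_table", "write_bundle"]

ESTIMATORS = ("bergman", "risch", "labuda")


@dataclass
class AnalysisResult:
    """Library-level result of one dating run (report numbers equal these
    values exactly; rounding happens only in display strings)."""

    per_marker: pd.DataFrame
    summaries: dict[str, TmrcaSummary]
    conserved: object | None
    demography: dict | None = None

    def summary_json(self) -> dict:
        out: dict = {"estimators": {}}
        for name, s in self.summaries.items():
            out["estimators"][name] = {
                "markers": list(s.markers),
                "mean_generations": s.mean,
                "se": s.se,
                "ci95": list(s.ci95) if s.ci95 else None,
                "years": s.years,
                "display": s.report(),
            }
        if self.conserved is not None:
            out["conserved_region"] = {
                "markers": list(self.conserved.markers),
                "genetic_length_cm": self.conserved.genetic_length_cm,
                "shared_alleles": {k: str(v) for k, v in self.conserved.shared_alleles.items()},
            }
        if self.demography is not None:
            out["demography"] = self.demography
        return out


def run_analysis(
    disease: ChromosomePanel,
    control: ChromosomePanel,
    estimators: Sequence[str] = ESTIMATORS,
    growth_rate_p: float = 0.0,
    generation_time: float = 30.0,
    overrides: Sequence[tuple[str, str, str]] = (),
    demography_block: Mapping | None = None,
) -> AnalysisResult:
    """Run the dating pipeline on phased disease and control panels.

    Markers where an estimator is non-informative get a reason code in the
    per-marker table rather than aborting the run; an estimator with no
    informative marker at all is reported with an empty summary row.
    """
    for est in estimators:
        if est not in ESTIMATORS:
            raise ValueError(f"unknown estimator {est!r}")
    region = conserved_region(disease) if disease.n >= 2 else None

    inputs: list[MarkerAgeInput] = []
    fa_by_marker: dict[str, Hashable] = {}
    for m in disease.markers:
        try:
            fa = founder_allele(m.name, disease, region)
        except ValueError:
            continue
        p_n = allele_frequency(m.name, control).get(fa.allele, 0.0) if control.n else 0.0
        fa_by_marker[m.name] = fa.allele
        inputs.append(MarkerAgeInput(marker=m, p_d=fa.p_d, p_n=p_n, founder_allele=fa.allele))

    rows: dict[str, dict] = {
        inp.marker.name: {
            "marker": inp.marker.name,
            "founder_allele": inp.founder_allele,
            "distance_mb": inp.marker.distance_mb,
            "side": inp.marker.side.value,
            "cM": inp.marker.genetic_distance,
            "theta": inp.resolved_theta(),
            "p_d": inp.p_d,
            "p_n": inp.p_n,
            "delta": inp.delta,
        }
        for inp in inputs
    }
    summaries: dict[str, TmrcaSummary] = {}
    for est in estimators:
        included, excluded = informativeness_filter(inputs, est, overrides)
        for inp, reason in excluded:
            rows[inp.marker.name][est] = math.nan
            rows[inp.marker.name][f"{est}_reason"] = reason
        values: dict[str, float] = {}
        for inp in included:
            theta = inp.resolved_theta()
            if est == "bergman":
                g = bergman_g(inp.p_d, inp.p_n, theta)
            else:
                g = risch_g(inp.delta, theta)
                if est == "labuda":
                    g = labuda_correct(g, growth_rate_p, theta)
            rows[inp.marker.name][est] = g
            if math.isnan(g):
                rows[inp.marker.name][f"{est}_reason"] = "allele_not_enriched"
            else:
                values[inp.marker.name] = g
        if values:
            summaries[est] = average_tmrca(values, generation_time=generation_time, estimator=est)

    per_marker = pd.DataFrame(list(rows.values()))
    demo = dict(demography_block) if demography_block is not None else None
    return AnalysisResult(
        per_marker=per_marker, summaries=summaries, conserved=region, demography=demo
    )


def average_table(
    generations: Mapping[str, Mapping[str, float]],
    generation_time: float = 30.0,
) -> dict[str, TmrcaSummary]:
    """Average prefilled per-marker generation values per estimator.

    ``generations`` maps estimator name to ``{marker: generations}``; this is
    the entry point for reproducing a published per-marker table's average
    rows when the underlying allele frequencies are unavailable.
    """
    return {
        est: average_tmrca(vals, generation_time=generation_time, estimator=est)
        for est, vals in generations.items()
        if vals
    }


def demography_report(
    census: CensusPair,
    homozygote_counts: Mapping[str, int] | None = None,
    n_cases: int | None = None,
) -> dict:
    """Demography block: growth rate, HWE allele frequencies, prevalence."""
    gr = growth_rate(census)
    out: dict = {
        "census": {
            "present": census.present,
            "reference": census.reference,
            "present_year": census.present_year,
            "reference_year": census.reference_year,
            "generation_time": census.generation_time,
        },
        "generations_between_censuses": gr.generations,
        "growth_rate_per_generation": gr.rate,
    }
    if homozygote_counts:
        out["hwe_allele_frequencies"] = {
            name: hwe_allele_freq(k, census.present) for name, k in homozygote_counts.items()
        }
    if n_cases is not None:
        prev = prevalence(n_cases, census.present)
        out["prevalence"] = {"ratio": str(prev), "k": prev.k, "k_exact": prev.k_exact}
    return out


def write_bundle(
    result: AnalysisResult,
    out_dir: str | Path,
    inputs: Mapping[str, str] | None = None,
    seed: int | None = None,
) -> Path:
    """Write the report bundle (TSVs, JSON summary, manifest) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.per_marker.to_csv(out / "per_marker.tsv", sep="\t", index=False)
    summary = result.summary_json()
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    lines = ["estimator\tn_markers\tgenerations\tyears"]
    for name, s in result.summaries.items():
        lines.append(f"{name}\t{s.n}\t{s.report()}\t{s.years:.0f}")
    (out / "summary.tsv").write_text("\n".join(lines) + "\n")
    manifest = {
        "package": "founderage",
        "version": __version__,
        "seed": seed,
        "inputs": dict(inputs or {}),
        "summary_sha256": hashlib.sha256(
            json.dumps(summary, sort_keys=True).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
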