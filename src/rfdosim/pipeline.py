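"""End-to-end stochastic dosimetry study.

Orchestrates the comparison of a reference phantom with its individualized
counterpart under random body positioning:

1. deterministic SAR metrics at the standard position (zero pose) for both
   phantoms, with reference-convention deviations;
2. one shared Latin-hypercube design over (Z-shift, tilt), evaluated
   through the forward model for each phantom;
3. a sparse polynomial-chaos surrogate per metric per phantom, with the
   degree chosen adaptively by the corrected leave-one-out criterion;
4. a large Monte-Carlo draw of the pose distribution pushed through the
   surrogates, yielding empirical SAR distributions (percentile tables and
   histograms);
5. percentile-level deviations between the two phantoms, using the
   reference model in the denominator.

Sharing one pose design between the phantoms removes design noise from the
comparison.  All randomness flows from the explicit seeds in the config;
rerunning an identical config reproduces the report bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from . import pce
from .forward import CoilField, Pose, SARResult, compute_sar_result, psar10g, sar_field, wb_sar, hd_sar, normalize_sar
from .phantoms import TissuePropertyTable, VoxelPhantom, read_phantom, weight_deviation_pct
from .pce import (
    ExperimentalDesign,
    InputDistribution,
    PCSurrogate,
    fit_lar,
    lhs_design,
    sample_distribution,
)
from .synthetic import PhantomRecipe, make_fixture_pair

__all__ = [
    "StudyConfig",
    "SARDistribution",
    "StudyReport",
    "REPORTED_PERCENTILES",
    "forward_metrics",
    "evaluate_design",
    "fit_adaptive_degree",
    "sar_distribution",
    "percentile_deviation",
    "surrogate_vs_montecarlo",
    "run_study",
]

REPORTED_PERCENTILES = (5.0, 25.0, 50.0, 75.0, 95.0)
METRICS = ("wbsar", "psar10g")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Everything a reproducible study run needs.

    Phantoms come either from disk (``ref_phantom``/``ind_phantom`` paths
    with their table paths) or from the synthetic generator
    (``phantom_seed`` + ``perturbation``).  All seeds are explicit.
    """

    # phantom source
    ref_phantom: str | None = None
    ref_table: str | None = None
    ind_phantom: str | None = None
    ind_table: str | None = None
    phantom_seed: int = 0
    perturbation: float = 0.04
    # coil
    frequency: float = 64e6
    b1: float = 1e-6
    coil_length: float = 0.04
    taper_length: float = 0.18
    table_offset: float = 0.05
    tilt_axis: Literal["long", "pitch"] = "long"
    # pose distribution (truncated Gaussians)
    z_shift_sd: float = 0.10 / 3.0
    z_shift_bound: float = 0.10
    tilt_sd: float = 5.0 / 3.0
    tilt_bound: float = 5.0
    # surrogate settings
    n_design: int = 100
    p_range: tuple[int, ...] = (1, 2, 3, 4, 5)
    threshold: float = 0.01
    m_draws: int = 100_000
    # seeds
    design_seed: int = 2024
    distribution_seed: int = 2025
    # output
    normalization: Literal["raw_B1", "absorbed_power_1W"] = "raw_B1"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.n_design < 3:
            raise ValueError("design size must be >= 3")
        if self.m_draws < 1:
            raise ValueError("m_draws must be >= 1")

    def coil(self) -> CoilField:
        return CoilField(
            frequency=self.frequency,
            b1=self.b1,
            length=self.coil_length,
            taper_length=self.taper_length,
            table_offset=self.table_offset,
            tilt_axis=self.tilt_axis,
        )

    def pose_distribution(self) -> InputDistribution:
        return InputDistribution(
            names=("z_shift_m", "tilt_deg"),
            mean=(0.0, 0.0),
            sd=(self.z_shift_sd, self.tilt_sd),
            lower=(-self.z_shift_bound, -self.tilt_bound),
            upper=(self.z_shift_bound, self.tilt_bound),
        )

    def phantoms(
        self,
    ) -> tuple[VoxelPhantom, TissuePropertyTable, VoxelPhantom, TissuePropertyTable]:
        if self.ref_phantom is not None:
            if None in (self.ref_table, self.ind_phantom, self.ind_table):
                raise ValueError("phantom paths must be given for both models")
            ref, ref_props = read_phantom(self.ref_phantom, self.ref_table)
            ind, ind_props = read_phantom(self.ind_phantom, self.ind_table)
            return ref, ref_props, ind, ind_props
        recipe = PhantomRecipe(seed=self.phantom_seed)
        return make_fixture_pair(recipe, perturbation=self.perturbation)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "p_range" in data:
            data["p_range"] = tuple(data["p_range"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["p_range"] = list(d["p_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# Forward evaluation of a design
# ---------------------------------------------------------------------------


def forward_metrics(
    phantom: VoxelPhantom,
    props: TissuePropertyTable,
    coil: CoilField,
    pose: Pose,
    normalization: str = "raw_B1",
) -> dict[str, float]:
    """One deterministic evaluation: wbSAR, hdSAR and pSAR10g from one field."""
    sar = sar_field(phantom, props, coil, pose)
    sar = normalize_sar(sar, phantom, props, normalization)  # type: ignore[arg-type]
    peak, _ = psar10g(sar, phantom, props)
    return {
        "wbsar": wb_sar(sar, phantom, props),
        "hdsar": hd_sar(sar, phantom, props),
        "psar10g": peak,
    }


def evaluate_design(
    phantom: VoxelPhantom,
    props: TissuePropertyTable,
    coil: CoilField,
    design: ExperimentalDesign,
    normalization: str = "raw_B1",
) -> dict[str, np.ndarray]:
    """Deterministic SAR metrics at every design pose (one field per pose)."""
    out: dict[str, list[float]] = {m: [] for m in METRICS}
    for row in design.poses:
        metrics = forward_metrics(
            phantom, props, coil, Pose(float(row[0]), float(row[1])), normalization
        )
        for m in METRICS:
            out[m].append(metrics[m])
    return {m: np.asarray(v) for m, v in out.items()}


def fit_adaptive_degree(
    design: ExperimentalDesign,
    observations: np.ndarray,
    p_range: Sequence[int] = (1, 2, 3, 4, 5),
    threshold: float = 0.01,
    metric: str = "",
) -> PCSurrogate:
    """Degree-adaptive fit on a fixed design.

    Accepts the first degree whose relative corrected leave-one-out error
    1 - Q^2 meets the threshold; otherwise returns the best fit with its
    warning flag set.
    """
    best: PCSurrogate | None = None
    for p in p_range:
        if pce.basis_size(design.dist.k, p) >= design.n:
            continue
        surrogate = fit_lar(design, observations, p, metric=metric)
        if best is None or surrogate.rel_error < best.rel_error:
            best = surrogate
        if surrogate.rel_error <= threshold:
            return surrogate
    if best is None:
        raise ValueError("design too small for every candidate degree")
    best.warning = True
    return best


# ---------------------------------------------------------------------------
# SAR distributions
# ---------------------------------------------------------------------------


@dataclass
class SARDistribution:
    """Empirical distribution of a SAR metric under the pose distribution."""

    metric: str
    samples: np.ndarray
    percentiles: dict[float, float]
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    provenance: dict

    @property
    def m(self) -> int:
        return len(self.samples)

    def percentile(self, q: float) -> float:
        # linear interpolation between order statistics
        return float(np.percentile(self.samples, q))

    def to_dict(self, with_samples: bool = False) -> dict:
        d = {
            "metric": self.metric,
            "m": self.m,
            "percentiles": {str(q): v for q, v in self.percentiles.items()},
            "hist_edges": self.hist_edges.tolist(),
            "hist_counts": self.hist_counts.tolist(),
            "provenance": self.provenance,
        }
        if with_samples:
            d["samples"] = self.samples.tolist()
        return d


def sar_distribution(
    surrogate: PCSurrogate,
    dist: InputDistribution,
    m_draws: int = 100_000,
    seed: int = 0,
    n_bins: int = 50,
    percentiles: Sequence[float] = REPORTED_PERCENTILES,
) -> SARDistribution:
    """Push a Monte-Carlo pose draw through the surrogate."""
    poses = sample_distribution(m_draws, dist, seed)
    samples = surrogate(poses)
    counts, edges = np.histogram(samples, bins=n_bins)
    return SARDistribution(
        metric=surrogate.metric,
        samples=samples,
        percentiles={float(q): float(np.percentile(samples, q)) for q in percentiles},
        hist_edges=edges,
        hist_counts=counts,
        provenance={
            "surrogate_metric": surrogate.metric,
            "surrogate_n": surrogate.n,
            "surrogate_p": surrogate.p,
            "design_seed": surrogate.seed,
            "distribution_seed": seed,
        },
    )


def percentile_deviation(
    dist_ref: SARDistribution, dist_ind: SARDistribution, q: float
) -> float:
    """(individual - reference) / reference x 100 at the q-th percentile."""
    if dist_ref.metric != dist_ind.metric:
        raise ValueError("distributions compare different metrics")
    if not 0.0 < q < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    ref = dist_ref.percentile(q)
    if ref == 0:
        raise ZeroDivisionError("reference percentile is zero")
    return (dist_ind.percentile(q) - ref) / ref * 100.0


def surrogate_vs_montecarlo(
    phantom: VoxelPhantom,
    props: TissuePropertyTable,
    coil: CoilField,
    surrogate: PCSurrogate,
    metric: str,
    n_mc: int = 200,
    seed: int = 7,
    percentiles: Sequence[float] = (50.0, 95.0),
    normalization: str = "raw_B1",
) -> dict:
    """Validate a surrogate against direct forward Monte-Carlo.

    The same pose samples are pushed through both the surrogate and the
    forward model; reports the per-percentile relative gaps and their
    maximum.
    """
    poses = sample_distribution(n_mc, surrogate.dist, seed)
    pred = surrogate(poses)
    direct = np.array(
        [
            forward_metrics(
                phantom, props, coil, Pose(float(r[0]), float(r[1])), normalization
            )[metric]
            for r in poses
        ]
    )
    gaps = {}
    for q in percentiles:
        d = float(np.percentile(direct, q))
        s = float(np.percentile(pred, q))
        gaps[float(q)] = abs(s - d) / abs(d) if d != 0 else np.inf
    return {
        "metric": metric,
        "n_mc": n_mc,
        "seed": seed,
        "percentile_rel_gap": gaps,
        "max_rel_gap": max(gaps.values()),
    }


# ---------------------------------------------------------------------------
# Study report
# ---------------------------------------------------------------------------


@dataclass
class StudyReport:
    """All artifacts of one study run."""

    config: StudyConfig
    standard_position: dict[str, SARResult]  # "reference" / "individual"
    surrogates: dict[str, PCSurrogate]  # "<model>:<metric>"
    distributions: dict[str, SARDistribution]  # "<model>:<metric>"
    deviations: pd.DataFrame  # metric x percentile deviation table

    def to_json(self) -> str:
        d = {
            "config": {
                **{
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(self.config).items()
                }
            },
            "standard_position": {
                model: json.loads(res.to_json())
                for model, res in self.standard_position.items()
            },
            "standard_position_deviation_pct": self.standard_deviation_rows(),
            "surrogate_diagnostics": {
                key: {
                    "metric": s.metric,
                    "n": s.n,
                    "p": s.p,
                    "n_active": s.n_active,
                    "eps_loo": s.eps_loo,
                    "q2": s.q2,
                    "rel_error": s.rel_error,
                    "warning": s.warning,
                }
                for key, s in self.surrogates.items()
            },
            "distributions": {
                key: dist.to_dict() for key, dist in self.distributions.items()
            },
            "percentile_deviations_pct": {
                m: {
                    str(q): float(
                        self.deviations.loc[
                            (self.deviations["metric"] == m)
                            & (self.deviations["percentile"] == q),
                            "deviation_pct",
                        ].iloc[0]
                    )
                    for q in REPORTED_PERCENTILES
                }
                for m in METRICS
            },
        }
        return json.dumps(d, indent=2)

    def standard_deviation_rows(self) -> dict[str, float]:
        ref = self.standard_position["reference"]
        ind = self.standard_position["individual"]
        return {
            "wbsar": weight_deviation_pct(ref.wbsar, ind.wbsar),
            "hdsar": weight_deviation_pct(ref.hdsar, ind.hdsar),
            "psar10g": weight_deviation_pct(ref.psar10g, ind.psar10g),
        }

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "study_report.json").write_text(self.to_json())
        self.deviations.to_csv(out / "percentile_deviations.csv", index=False)
        rows = []
        for key, dist in self.distributions.items():
            for q, v in dist.percentiles.items():
                rows.append({"series": key, "percentile": q, "value_W_per_kg": v})
        pd.DataFrame(rows).to_csv(out / "percentiles.csv", index=False)
        hist_rows = []
        for key, dist in self.distributions.items():
            for lo, hi, c in zip(
                dist.hist_edges[:-1], dist.hist_edges[1:], dist.hist_counts
            ):
                hist_rows.append(
                    {"series": key, "bin_lo": lo, "bin_hi": hi, "count": int(c)}
                )
        pd.DataFrame(hist_rows).to_csv(out / "histograms.csv", index=False)
        for key, s in self.surrogates.items():
            (out / f"surrogate_{key.replace(':', '_')}.json").write_text(s.to_json())
        return out / "study_report.json"


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full stochastic comparison study (see module docstring)."""
    ref, ref_props, ind, ind_props = config.phantoms()
    coil = config.coil()
    dist = config.pose_distribution()

    standard = {
        "reference": compute_sar_result(
            ref, ref_props, coil, Pose(), config.normalization
        ),
        "individual": compute_sar_result(
            ind, ind_props, coil, Pose(), config.normalization
        ),
    }

    design = lhs_design(config.n_design, dist, config.design_seed)
    surrogates: dict[str, PCSurrogate] = {}
    distributions: dict[str, SARDistribution] = {}
    for model, phantom, props in (
        ("reference", ref, ref_props),
        ("individual", ind, ind_props),
    ):
        observations = evaluate_design(
            phantom, props, coil, design, config.normalization
        )
        for metric in METRICS:
            key = f"{model}:{metric}"
            surrogate = fit_adaptive_degree(
                design,
                observations[metric],
                config.p_range,
                config.threshold,
                metric=metric,
            )
            surrogates[key] = surrogate
            distributions[key] = sar_distribution(
                surrogate,
                dist,
                m_draws=config.m_draws,
                seed=config.distribution_seed,
            )

    rows = []
    for metric in METRICS:
        for q in REPORTED_PERCENTILES:
            rows.append(
                {
                    "metric": metric,
                    "percentile": q,
                    "reference": distributions[f"reference:{metric}"].percentiles[q],
                    "individual": distributions[f"individual:{metric}"].percentiles[q],
                    "deviation_pct": percentile_deviation(
                        distributions[f"reference:{metric}"],
                        distributions[f"individual:{metric}"],
                        q,
                    ),
                }
            )
    report = StudyReport(
        config=config,
        standard_position=standard,
        surrogates=surrogates,
        distributions=distributions,
        deviations=pd.DataFrame(rows),
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report
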