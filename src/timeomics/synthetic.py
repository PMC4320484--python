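"""Synthetic multi-omics data with known ground truth.

Emulates a nitrogen-starvation/recovery time course: 6 sampling times
(0, 5, 24, 72, 77, 96 h; starvation between the first and fourth sampling,
recovery afterwards) with 4 biological replicates each. The generator plants

* *responders* — proteins with a multiplicative time profile (induced or
  repressed, up to ``effect_size``-fold, peaking during starvation),
* *correlated blocks* — groups of proteins, metabolites and physiological
  variables sharing a latent factor, with within-block pairwise correlation
  ``factor_loading`` in absolute value (members load with alternating sign,
  as starvation drives some pools up and others down; this also keeps any
  one block from dominating per-sample totals),
* *lag-1 causal pairs* — white-noise driver series and targets following the
  driver with one step of delay,
* *MCAR missingness* — a fixed number of cells blanked uniformly at random,

so that every downstream stage (filtering, imputation, univariate tests,
sPLS, networks, Granger screening, profiling) has a recoverable answer.

Spectral counts follow a Poisson law around the length-weighted expectation
``depth * L_k * a_ks / sum_j L_j * a_js`` — the simplest count law under
which NSAF is an unbiased plug-in estimator of relative abundance ``a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .datatypes import SpectralCountTable, TruthRecord
from .errors import InvalidDesignError, ParameterError

__all__ = [
    "DesignSpec",
    "SimParams",
    "TruthConfig",
    "generate_design",
    "latent_factors",
    "simulate_proteome",
    "simulate_metabolome_physio",
    "simulate_causal_series",
    "inject_missingness",
    "simulate_dataset",
    "SimulatedDataset",
    "write_dataset",
]

DEFAULT_TIMEPOINTS = (0.0, 5.0, 24.0, 72.0, 77.0, 96.0)


@dataclass(frozen=True)
class DesignSpec:
    """Sampling design: ordered timepoints (h) x biological replicates."""

    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.timepoints) == 0:
            raise InvalidDesignError("at least one timepoint is required")
        diffs = np.diff(np.asarray(self.timepoints, dtype=float))
        if len(diffs) and not (diffs > 0).all():
            raise InvalidDesignError(
                f"timepoints must be strictly increasing, got {self.timepoints}"
            )
        if self.n_replicates < 1:
            raise InvalidDesignError("n_replicates must be >= 1")


@dataclass(frozen=True)
class SimParams:
    """Free parameters of the generative model.

    depth is the expected total PSM per sample; effect_size the maximum fold
    change of responder profiles; factor_loading the within-block pairwise
    correlation; dropout_threshold the expected-count level below which
    detection fails (deterministic); noise_sd the innovation SD of causal
    target series; rep_noise_sd the natural-log SD of replicate noise;
    baseline_sigma the natural-log SD of between-feature baselines.
    """

    n_proteins: int = 500
    n_metabolites: int = 50
    n_physio: int = 5
    length_range: tuple[int, int] = (100, 1500)
    depth: float = 20000.0
    effect_size: float = 4.0
    factor_loading: float = 0.9
    dropout_threshold: float = 1.0
    missing_rate: float = 0.05
    series_length: int = 50
    noise_sd: float = 0.1
    rep_noise_sd: float = 0.2
    baseline_sigma: float = 0.8
    block_amplitude: float = 1.5

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_metabolites) < 1 or self.n_physio < 0:
            raise ParameterError("feature counts must be positive (n_physio may be 0)")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ParameterError(f"invalid length_range {self.length_range}")
        if self.depth <= 0 or self.effect_size < 1 or self.noise_sd <= 0:
            raise ParameterError("depth, effect_size, noise_sd must be positive (effect_size >= 1)")
        if not (0 < self.factor_loading <= 1):
            raise ParameterError("factor_loading must lie in (0, 1]")
        if self.dropout_threshold < 0:
            raise ParameterError("dropout_threshold must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ParameterError("missing_rate must lie in [0, 1)")
        if self.rep_noise_sd < 0 or self.baseline_sigma < 0:
            raise ParameterError("noise scales must be >= 0")
        if self.block_amplitude <= 0:
            raise ParameterError("block_amplitude must be > 0")


@dataclass(frozen=True)
class TruthConfig:
    """How much ground truth to plant."""

    responder_fraction: float = 0.1
    n_factors: int = 3
    proteins_per_block: int = 10
    metabolites_per_block: int = 5
    n_causal_pairs: int = 5
    n_null_series: int = 10
    causal_beta: float = 0.9

    def __post_init__(self) -> None:
        if not (0 <= self.responder_fraction <= 1):
            raise ParameterError("responder_fraction must lie in [0, 1]")
        if min(self.n_factors, self.n_causal_pairs, self.n_null_series) < 0:
            raise ParameterError("counts must be nonnegative")


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """One record per (timepoint, replicate) with IDs ``T<h>_R<r>``."""
    records = []
    for t in spec.timepoints:
        for r in range(1, spec.n_replicates + 1):
            records.append((f"T{_fmt_time(t)}_R{r}", float(t), r))
    design = pd.DataFrame(records, columns=["sample", "time_h", "replicate"])
    return design.set_index("sample")


def _fmt_time(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else str(t)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def condition_shape(n_timepoints: int) -> np.ndarray:
    """Starvation-response shape on [0, 1] per timepoint index.

    0 at the control start, 1 during starvation, decaying through early
    recovery back to 0 at the end — mirrors a deplete-then-replenish design.
    """
    s = np.zeros(n_timepoints)
    if n_timepoints >= 4:
        s[1 : n_timepoints - 2] = 1.0
        s[n_timepoints - 2] = 0.25
    elif n_timepoints in (2, 3):
        s[1] = 1.0
    return s


def condition_labels(timepoints) -> dict[float, str]:
    shape = condition_shape(len(timepoints))
    return {
        float(t): ("starved-like" if s >= 0.5 else "control-like")
        for t, s in zip(timepoints, shape)
    }


def latent_factors(design: pd.DataFrame, n_factors: int, rng) -> pd.DataFrame:
    """Per-sample latent factor values, standardized across samples.

    Each factor follows a smooth time shape (distinct cosine harmonics over
    the timepoint grid) plus replicate-level noise, then is standardized so
    that block loadings translate directly into correlations.
    """
    rng = _rng(rng)
    times = np.sort(design["time_h"].unique())
    n_t = len(times)
    u = np.linspace(0.0, 1.0, n_t) if n_t > 1 else np.zeros(1)
    t_index = design["time_h"].map({t: i for i, t in enumerate(times)}).to_numpy()
    factors = np.empty((len(design), n_factors))
    for m in range(n_factors):
        shape = np.cos(np.pi * (m + 1) * u)
        values = shape[t_index] + rng.normal(0.0, 0.3, size=len(design))
        values = values - values.mean()
        sd = values.std()
        factors[:, m] = values / sd if sd > 0 else values
    return pd.DataFrame(factors, index=design.index, columns=[f"F{m}" for m in range(n_factors)])


def _block_signal(factor: np.ndarray, loading: float, rng: np.random.Generator) -> np.ndarray:
    """One block member's unit-variance log signal: sqrt(rho)*f + sqrt(1-rho)*eps."""
    eps = rng.normal(0.0, 1.0, size=factor.shape)
    return np.sqrt(loading) * factor + np.sqrt(1.0 - loading) * eps


def simulate_proteome(
    design: pd.DataFrame,
    params: SimParams = SimParams(),
    truth_cfg: TruthConfig = TruthConfig(),
    rng=0,
    factors: pd.DataFrame | None = None,
) -> tuple[SpectralCountTable, TruthRecord]:
    """Spectral counts with planted responders and correlated blocks.

    Latent relative abundance per protein k and sample s is
    ``a_ks = baseline_k * profile_k(t(s)) * exp(noise)``; the expected PSM is
    ``depth * L_k * a_ks / sum_j L_j a_js`` and observed counts are Poisson
    draws, zeroed where the expectation falls below ``dropout_threshold``.
    """
    rng = _rng(rng)
    n = params.n_proteins
    samples = design.index
    times = np.sort(design["time_h"].unique())
    t_index = design["time_h"].map({t: i for i, t in enumerate(times)}).to_numpy()

    width = max(4, len(str(n)))
    ids = [f"P{i + 1:0{width}d}" for i in range(n)]
    lengths = rng.integers(params.length_range[0], params.length_range[1] + 1, size=n)
    log_baseline = rng.normal(0.0, params.baseline_sigma, size=n)

    # responders: alternating induced / repressed starvation profiles,
    # drawn from the quantifiable pool (a repressed responder whose control
    # abundance already sits at the detection limit falls below the printed
    # minimum-abundance/presence filters and is unrecoverable by design)
    n_resp = int(round(truth_cfg.responder_fraction * n))
    quant_score = log_baseline + np.log(lengths)
    quantifiable = np.where(
        (log_baseline >= np.quantile(log_baseline, 0.35))
        & (quant_score >= np.quantile(quant_score, 0.35))
    )[0]
    if n_resp > len(quantifiable):
        quantifiable = np.arange(n)
    responder_idx = np.sort(rng.choice(quantifiable, size=n_resp, replace=False))
    shape = condition_shape(len(times))
    log_profile = np.zeros((n, len(times)))
    responders: dict[str, list[float]] = {}
    for j, k in enumerate(responder_idx):
        direction = 1.0 if j % 2 == 0 else -1.0
        log_profile[k] = direction * shape * np.log(params.effect_size)
        responders[ids[k]] = np.exp(log_profile[k]).tolist()

    # correlated blocks drawn from the well-quantified (above-median baseline)
    # non-responder pool: spectral-count correlation structure is only
    # observable for confidently quantified proteins, so that is where the
    # generator plants it
    membership: dict[str, int] = {}
    n_members = truth_cfg.n_factors * truth_cfg.proteins_per_block
    pool = np.setdiff1d(np.arange(n), responder_idx)
    member_idx = np.array([], dtype=int)
    if n_members > 0 and truth_cfg.n_factors > 0:
        if n_members > len(pool):
            raise ParameterError("not enough non-responder proteins for the requested blocks")
        quantified = log_baseline[pool] + np.log(lengths[pool])  # ~ log expected counts
        abundant = pool[quantified >= np.quantile(quantified, 0.5)]
        if n_members <= len(abundant):
            pool = abundant
        member_idx = np.sort(rng.choice(pool, size=n_members, replace=False))
        if factors is None:
            factors = latent_factors(design, truth_cfg.n_factors, rng)
        for j, k in enumerate(member_idx):
            membership[ids[k]] = j % truth_cfg.n_factors

    # replicate noise: block members use their factor residual as replicate
    # noise (so the planted correlation survives quantitation); the rest get
    # plain lognormal replicate noise.
    log_noise = rng.normal(0.0, params.rep_noise_sd, size=(n, len(samples)))
    for j, k in enumerate(member_idx):
        m = membership[ids[k]]
        sign = 1.0 if (j // truth_cfg.n_factors) % 2 == 0 else -1.0
        log_noise[k] = sign * params.block_amplitude * _block_signal(
            factors.iloc[:, m].to_numpy(), params.factor_loading, rng
        )

    log_a = log_baseline[:, None] + log_profile[:, t_index] + log_noise
    a = np.exp(log_a)
    weighted = lengths[:, None] * a
    expected = params.depth * weighted / weighted.sum(axis=0, keepdims=True)
    observed = rng.poisson(expected).astype(np.int64)
    observed[expected < params.dropout_threshold] = 0

    counts = pd.DataFrame(observed, index=ids, columns=samples)
    table = SpectralCountTable(counts=counts, lengths=pd.Series(lengths, index=ids, name="length"))
    truth = TruthRecord(
        responders=responders,
        block_memberships=membership,
        condition_labels=condition_labels(times),
        expected_psm=pd.DataFrame(expected, index=ids, columns=samples),
    )
    return table, truth


#: physiological variable names; the first mirrors a ratio left un-normalized
PHYSIO_NAMES = ("FvFm", "FW", "lipids")


def simulate_metabolome_physio(
    design: pd.DataFrame,
    params: SimParams = SimParams(),
    truth_cfg: TruthConfig = TruthConfig(),
    rng=0,
    factors: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Metabolite peak areas and physiology driven by shared latent factors.

    Block-member metabolites share the factor of their block on the log
    scale; physiological variables are noisy affine images of designated
    factors. Peak areas are strictly positive (lognormal).
    """
    rng = _rng(rng)
    if not (0 < params.factor_loading <= 1):
        raise ParameterError("factor_loading must lie in (0, 1]")
    samples = design.index
    n_met, n_phys = params.n_metabolites, params.n_physio
    if factors is None and truth_cfg.n_factors > 0:
        factors = latent_factors(design, truth_cfg.n_factors, rng)

    ids = [f"M{i + 1:03d}" for i in range(n_met)]
    log_baseline = rng.normal(10.0, params.baseline_sigma, size=n_met)
    log_area = log_baseline[:, None] + rng.normal(0.0, params.rep_noise_sd, size=(n_met, len(samples)))

    membership: dict[str, int] = {}
    n_members = truth_cfg.n_factors * truth_cfg.metabolites_per_block
    if n_members > 0 and truth_cfg.n_factors > 0:
        if n_members > n_met:
            raise ParameterError("not enough metabolites for the requested blocks")
        member_idx = np.sort(rng.choice(n_met, size=n_members, replace=False))
        for j, k in enumerate(member_idx):
            m = j % truth_cfg.n_factors
            membership[ids[k]] = m
            sign = 1.0 if (j // truth_cfg.n_factors) % 2 == 0 else -1.0
            log_area[k] = log_baseline[k] + sign * params.block_amplitude * _block_signal(
                factors.iloc[:, m].to_numpy(), params.factor_loading, rng
            )
    metabolites = pd.DataFrame(np.exp(log_area), index=ids, columns=samples)

    phys_names = [
        PHYSIO_NAMES[i] if i < len(PHYSIO_NAMES) else f"phys{i + 1}" for i in range(n_phys)
    ]
    phys_values = np.empty((n_phys, len(samples)))
    for v in range(n_phys):
        m = v % truth_cfg.n_factors if truth_cfg.n_factors > 0 else None
        signal = factors.iloc[:, m].to_numpy() if m is not None else 0.0
        phys_values[v] = 2.0 + 0.5 * signal + rng.normal(0.0, 0.1, size=len(samples))
        if m is not None:
            membership[phys_names[v]] = m
    physio = pd.DataFrame(phys_values, index=phys_names, columns=samples)

    truth = TruthRecord(
        block_memberships=membership,
        condition_labels=condition_labels(np.sort(design["time_h"].unique())),
    )
    return metabolites, physio, truth


def simulate_causal_series(
    params: SimParams = SimParams(),
    truth_cfg: TruthConfig = TruthConfig(),
    rng=0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Driver/target/null series for the Granger stage.

    Drivers are standard Gaussian white noise; each target obeys
    ``y(t) = beta * x(t-1) + eps(t)`` with ``eps ~ N(0, noise_sd^2)``;
    null series are mutually independent white noise.
    """
    rng = _rng(rng)
    T = params.series_length
    if T < 10:
        raise ParameterError(f"series_length must be >= 10, got {T}")
    rows, names, pairs = [], [], []
    for i in range(truth_cfg.n_causal_pairs):
        x = rng.normal(0.0, 1.0, size=T)
        eps = rng.normal(0.0, params.noise_sd, size=T)
        y = eps.copy()
        y[1:] += truth_cfg.causal_beta * x[:-1]
        rows.extend([x, y])
        names.extend([f"X{i + 1:02d}", f"Y{i + 1:02d}"])
        pairs.append((f"X{i + 1:02d}", f"Y{i + 1:02d}", truth_cfg.causal_beta))
    for i in range(truth_cfg.n_null_series):
        rows.append(rng.normal(0.0, 1.0, size=T))
        names.append(f"N{i + 1:02d}")
    series = pd.DataFrame(rows, index=names, columns=[f"t{j}" for j in range(T)])
    return series, TruthRecord(causal_pairs=pairs)


def inject_missingness(
    table: pd.DataFrame, missing_rate: float, seed=0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank exactly round(rate * cells) entries completely at random.

    Never blanks an entire feature or an entire sample; returns the blanked
    table (NaN) and a boolean mask of blanked positions.
    """
    if not (0 <= missing_rate < 1):
        raise ParameterError("missing_rate must lie in [0, 1)")
    rng = _rng(seed)
    nr, nc = table.shape
    n_cells = nr * nc
    n_blank = int(round(missing_rate * n_cells))
    mask = pd.DataFrame(False, index=table.index, columns=table.columns)
    if n_blank == 0:
        return table.copy(), mask
    if n_cells - n_blank < max(nr, nc):
        raise ParameterError(
            f"missing_rate {missing_rate} would blank an entire row or column "
            f"of a {nr}x{nc} table"
        )
    flat = None
    for _ in range(200):  # uniform rejection sampling
        candidate = rng.choice(n_cells, size=n_blank, replace=False)
        m = np.zeros(n_cells, dtype=bool)
        m[candidate] = True
        m = m.reshape(nr, nc)
        if m.all(axis=1).any() or m.all(axis=0).any():
            continue
        flat = candidate
        break
    if flat is None:
        # constructive fallback: protect a random row/column cover, blank the rest
        row_perm, col_perm = rng.permutation(nr), rng.permutation(nc)
        protected = {
            (row_perm[i % nr], col_perm[i % nc]) for i in range(max(nr, nc))
        }
        free = np.array(
            [i for i in range(n_cells) if (i // nc, i % nc) not in protected]
        )
        flat = rng.choice(free, size=n_blank, replace=False)
    m = np.zeros(n_cells, dtype=bool)
    m[flat] = True
    m = m.reshape(nr, nc)
    arr = table.to_numpy(dtype=float).copy()
    arr[m] = np.nan
    blanked = pd.DataFrame(arr, index=table.index, columns=table.columns)
    mask = pd.DataFrame(m, index=table.index, columns=table.columns)
    return blanked, mask


@dataclass
class SimulatedDataset:
    """Bundle of everything one synthetic run produces."""

    design: pd.DataFrame
    proteome: SpectralCountTable
    metabolites: pd.DataFrame
    physio: pd.DataFrame
    causal_series: pd.DataFrame
    truth: TruthRecord


def simulate_dataset(
    spec: DesignSpec = DesignSpec(),
    params: SimParams = SimParams(),
    truth_cfg: TruthConfig = TruthConfig(),
) -> SimulatedDataset:
    """Generate all five input tables with shared latent factors.

    Deterministic given ``spec.seed``: per-stage generators are spawned from
    one seed sequence so tables are bit-identical across runs.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(5)
    design = generate_design(spec)
    factor_rng = np.random.default_rng(streams[0])
    factors = (
        latent_factors(design, truth_cfg.n_factors, factor_rng)
        if truth_cfg.n_factors > 0
        else None
    )
    proteome, truth_p = simulate_proteome(
        design, params, truth_cfg, rng=np.random.default_rng(streams[1]), factors=factors
    )
    metabolites, physio, truth_m = simulate_metabolome_physio(
        design, params, truth_cfg, rng=np.random.default_rng(streams[2]), factors=factors
    )
    series, truth_c = simulate_causal_series(
        params, truth_cfg, rng=np.random.default_rng(streams[3])
    )
    truth = truth_p.merge(truth_m).merge(truth_c)
    if params.missing_rate > 0:
        metabolites, mask = inject_missingness(
            metabolites, params.missing_rate, seed=np.random.default_rng(streams[4])
        )
        truth.missing_cells = [
            (f, s) for f in mask.index for s in mask.columns if mask.at[f, s]
        ]
    return SimulatedDataset(
        design=design,
        proteome=proteome,
        metabolites=metabolites,
        physio=physio,
        causal_series=series,
        truth=truth,
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path, seed: int | None = None) -> None:
    """Write the five input tables as TSV plus truth and a seed run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tio.write_design(dataset.design, outdir / "design.tsv")
    tio.write_feature_table(dataset.proteome.to_frame(), outdir / "spectral_counts.tsv", "protein")
    tio.write_feature_table(dataset.metabolites, outdir / "metabolites.tsv", "metabolite")
    tio.write_feature_table(dataset.physio, outdir / "physiology.tsv", "variable")
    tio.write_feature_table(dataset.causal_series, outdir / "causal_series.tsv", "series")
    dataset.truth.to_json(outdir / "truth.json")
    tio.write_json({"seed": seed}, outdir / "simulation_log.json")
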