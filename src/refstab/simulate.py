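"""Synthetic data generators with recorded ground truth.

Every generator returns both the dataset and a :class:`SimulationTruth`
record holding the construction parameters, so each pipeline stage can be
tested in a closed loop: the screening pass set, the noise-SD stability
order, the amplification efficiency and the target fold changes are all
known by construction and re-derivable by brute force from the truth.

The noise model is Gaussian on the Cq scale (multiplicative on transcript
abundance), the standard error structure of qPCR:

    Cq_{g,s} = a_g + t_{g, grp(s)} + delta_s + e_{g,s}

with per-gene baseline a_g, per-gene per-group shift t, per-sample loading
effect delta_s ~ N(0, sigma_load^2) (pipetting / input-amount variation,
shared by all genes of a sample) and per-well noise e ~ N(0, sigma_g^2).

All draws use numpy's default PCG64 generator seeded explicitly; identical
seeds give identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import AnalysisConfig, CqTable, ExpressionMatrix, ValidationError

DEFAULT_TISSUES = ("leaf", "rhizome", "root", "stem")


@dataclass
class SimulationTruth:
    """Ground-truth record of one simulated dataset."""

    seed: int
    baseline: pd.Series | None = None          # a_g (cycles) or mu_g (FPKM)
    sigma: pd.Series | None = None             # per-gene noise SD (cycles)
    group_shift: pd.DataFrame | None = None    # t_{g,i} (cycles), genes x groups
    sigma_load: float = 0.0                    # per-sample loading SD (cycles)
    e_true: float | None = None                # true amplification efficiency
    log2_fold_changes: pd.DataFrame | None = None  # targets x groups
    expected_pass: tuple[str, ...] = field(default=())
    expected_stability_order: tuple[str, ...] = field(default=())


def brute_force_screen(values: pd.DataFrame,
                       config: AnalysisConfig | None = None) -> list[str]:
    """Independent evaluation of the MV/MFC/CV screen, SD-ordered.

    Deliberately written from the raw definitions (plain numpy, no shared
    code with the screening module) so it can serve as an oracle.
    """
    config = config or AnalysisConfig()
    out = []
    for gene in values.index:
        x = values.loc[gene].to_numpy(dtype=float)
        mv = x.mean()
        sd = x.std(ddof=config.ddof)
        if x.min() <= 0:
            continue
        mfc = x.max() / x.min()
        cv = sd / mv if mv > 0 else np.inf
        if mv > config.mv_min and mfc < config.mfc_max and cv < config.cv_max:
            out.append((sd, str(gene)))
    return [g for _, g in sorted(out)]


def simulate_expression_matrix(
    n_stable: int,
    n_variable: int,
    n_samples: int = 12,
    config: AnalysisConfig | None = None,
    seed: int = 0,
    include_zero_gene: bool = False,
    include_constant_gene: bool = False,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """FPKM matrix with known stable and tissue-variable genes.

    Emulates a multi-tissue RNA-seq profile (default 4 tissues x 3
    replicates = 12 samples): stable genes have baseline FPKM above 60 and
    multiplicative noise with CV below 5%, so they satisfy the screening
    thresholds; variable genes receive per-tissue multipliers forcing a
    maximum fold change of at least 2, so they fail.  Optional edge genes:
    one with a zero FPKM entry (undefined MFC) and one exactly constant.
    The truth's ``expected_pass`` is evaluated by brute force on the
    realized matrix, never assumed from the construction.
    """
    if n_stable < 1 or n_variable < 0 or n_samples < 2:
        raise ValidationError("need n_stable >= 1, n_variable >= 0, n_samples >= 2")
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    tissues = [DEFAULT_TISSUES[i % len(DEFAULT_TISSUES)] for i in range(n_samples)]
    samples = [f"S{i+1:02d}_{t}" for i, (t) in enumerate(tissues)]

    rows = {}
    baseline = {}
    for i in range(n_stable):
        mu = rng.uniform(65.0, 220.0)
        cv = rng.uniform(0.005, 0.045)
        x = mu * (1.0 + rng.normal(0.0, cv, size=n_samples))
        rows[f"STB{i+1:02d}"] = np.clip(x, 0.0, None)
        baseline[f"STB{i+1:02d}"] = mu
    tissue_levels = sorted(set(tissues))
    for i in range(n_variable):
        mu = rng.uniform(20.0, 300.0)
        mult = rng.uniform(0.4, 1.0, size=len(tissue_levels))
        mult[rng.integers(len(tissue_levels))] *= rng.uniform(2.5, 5.0)
        per_sample = np.array([mult[tissue_levels.index(t)] for t in tissues])
        x = mu * per_sample * (1.0 + rng.normal(0.0, 0.05, size=n_samples))
        rows[f"VAR{i+1:02d}"] = np.clip(x, 0.0, None)
        baseline[f"VAR{i+1:02d}"] = mu
    if include_zero_gene:
        x = rng.uniform(60.0, 120.0, size=n_samples)
        x[rng.integers(n_samples)] = 0.0
        rows["ZERO01"] = x
        baseline["ZERO01"] = float(x.mean())
    if include_constant_gene:
        c = float(rng.uniform(60.0, 120.0))
        rows["CONST1"] = np.full(n_samples, c)
        baseline["CONST1"] = c

    values = pd.DataFrame(rows, index=samples).T
    values.index.name = "gene"
    expected = brute_force_screen(values, config)
    truth = SimulationTruth(
        seed=seed,
        baseline=pd.Series(baseline),
        expected_pass=tuple(expected),
    )
    return ExpressionMatrix(values), truth


def _default_group_sizes(groups: Sequence[int] | Mapping[str, int] | None,
                         n_samples: int | None) -> dict[str, int]:
    if groups is None:
        if n_samples is None:
            raise ValidationError("give either group sizes or n_samples")
        return {"G1": n_samples}
    if isinstance(groups, Mapping):
        return {str(k): int(v) for k, v in groups.items()}
    return {f"G{i+1}": int(n) for i, n in enumerate(groups)}


def simulate_cq_experiment(
    n_genes: int,
    n_samples: int | None = None,
    groups: Sequence[int] | Mapping[str, int] | None = None,
    sigma_profile: Sequence[float] | None = None,
    shifts: np.ndarray | pd.DataFrame | float = 0.0,
    sigma_load: float = 0.0,
    seed: int = 0,
    baseline: Sequence[float] | None = None,
) -> tuple[CqTable, SimulationTruth]:
    """Multi-group Cq experiment with gene-specific noise and group shifts.

    ``sigma_profile`` gives the per-gene noise SD in cycles (default 0.2
    for every gene); ``shifts`` a genes x groups array of group effects
    t_{g,i} (scalar 0 = none); ``sigma_load`` the SD of the per-sample
    loading effect shared by all genes.  The per-well noise stream is
    drawn independently of the loading stream, so runs that differ only in
    ``sigma_load`` share their residuals.

    The truth's ``expected_stability_order`` is the ascending-sigma gene
    order (the true stability order when shifts are zero).
    """
    if n_genes < 2:
        raise ValidationError("need at least 2 genes")
    sizes = _default_group_sizes(groups, n_samples)
    total = sum(sizes.values())
    if total < 3:
        raise ValidationError("need at least 3 samples")
    genes = [f"GENE{i+1:02d}" for i in range(n_genes)]
    group_levels = list(sizes)

    sigma = np.full(n_genes, 0.2) if sigma_profile is None else np.asarray(
        sigma_profile, dtype=float)
    if sigma.shape != (n_genes,) or (sigma < 0).any():
        raise ValidationError("sigma_profile must hold one SD >= 0 per gene")
    if np.isscalar(shifts):
        t = np.full((n_genes, len(group_levels)), float(shifts))
    else:
        t = (shifts.to_numpy(dtype=float) if isinstance(shifts, pd.DataFrame)
             else np.asarray(shifts, dtype=float))
        if t.shape != (n_genes, len(group_levels)):
            raise ValidationError(
                f"shifts must be {n_genes} genes x {len(group_levels)} groups"
            )

    rng = np.random.default_rng(seed)
    base_rng, noise_rng, load_rng = rng.spawn(3)
    a = (np.asarray(baseline, dtype=float) if baseline is not None
         else base_rng.uniform(18.0, 30.0, size=n_genes))

    sample_ids, sample_group, replicate = [], [], []
    for level, size in sizes.items():
        for r in range(size):
            sample_ids.append(f"{level}_R{r+1:02d}")
            sample_group.append(level)
            replicate.append(r + 1)
    group_idx = np.array([group_levels.index(g) for g in sample_group])

    e = noise_rng.normal(0.0, 1.0, size=(n_genes, total)) * sigma[:, None]
    delta = load_rng.normal(0.0, 1.0, size=total) * float(sigma_load)
    cq = a[:, None] + t[:, group_idx] + delta[None, :] + e

    meta = pd.DataFrame(
        {
            "group": sample_group,
            "condition": ["control" if g == group_levels[0] else "experiment"
                          for g in sample_group],
            "replicate": replicate,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    table = CqTable(pd.DataFrame(cq, index=pd.Index(genes, name="gene"),
                                 columns=sample_ids), meta)
    order = tuple(g for _, g in sorted(zip(sigma, genes)))
    truth = SimulationTruth(
        seed=seed,
        baseline=pd.Series(a, index=genes),
        sigma=pd.Series(sigma, index=genes),
        group_shift=pd.DataFrame(t, index=genes, columns=group_levels),
        sigma_load=float(sigma_load),
        expected_stability_order=order,
    )
    return table, truth


def simulate_dilution_series(
    e_true: float,
    intercept: float = 32.0,
    n_points: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """10-fold dilution series with a known amplification efficiency.

    Concentrations run 10^0 .. 10^-(n_points-1); Cq follows
    intercept - log10(c) / log10(1 + e_true) plus Gaussian noise.
    ``e_true`` is the efficiency as a fraction (1.0 = 100%).
    """
    if e_true <= 0:
        raise ValidationError("true efficiency must be positive")
    if n_points < 1:
        raise ValidationError("need at least one dilution point")
    rng = np.random.default_rng(seed)
    conc = 10.0 ** -np.arange(n_points, dtype=float)
    slope = -1.0 / np.log10(1.0 + e_true)
    cq = intercept + slope * np.log10(conc) + rng.normal(0.0, noise_sd, n_points)
    return list(zip(conc.tolist(), cq.tolist()))


def simulate_target_experiment(
    true_log2_fold_changes: Mapping[str, Mapping[str, float]],
    reference_baselines: Mapping[str, float] | None = None,
    target_baseline: float = 26.0,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    sigma_load: float = 0.0,
    seed: int = 0,
) -> tuple[CqTable, SimulationTruth]:
    """Target genes with known fold changes over a control, plus references.

    Emulates a postharvest-style time course: one control group plus one
    experiment group per fold-change key.  A target with log2 fold change
    f in group i sits f cycles *below* its control Cq there (one cycle per
    doubling), so ddCq quantification should recover RQ = 2^f.  Reference
    genes are flat across groups (default two, baselines 22 and 24).
    """
    if n_replicates < 2:
        raise ValidationError("need at least 2 replicates per group")
    refs = dict(reference_baselines) if reference_baselines else {
        "REF1": 22.0, "REF2": 24.0}
    targets = list(true_log2_fold_changes)
    exp_groups: list[str] = []
    for fc in true_log2_fold_changes.values():
        for grp in fc:
            if grp not in exp_groups:
                exp_groups.append(grp)
    groups = ["control"] + exp_groups
    genes = list(refs) + targets

    shift = np.zeros((len(genes), len(groups)))
    for ti, tgt in enumerate(targets):
        for grp, f in true_log2_fold_changes[tgt].items():
            shift[len(refs) + ti, groups.index(grp)] = -float(f)
    baselines = np.array(list(refs.values())
                         + [target_baseline] * len(targets))

    table, _ = simulate_cq_experiment(
        n_genes=len(genes),
        groups={g: n_replicates for g in groups},
        sigma_profile=[noise_sd] * len(genes),
        shifts=shift,
        sigma_load=sigma_load,
        seed=seed,
        baseline=baselines,
    )
    cq = table.cq.copy()
    cq.index = pd.Index(genes, name="gene")
    truth = SimulationTruth(
        seed=seed,
        baseline=pd.Series(baselines, index=genes),
        sigma=pd.Series(noise_sd, index=genes),
        sigma_load=float(sigma_load),
        log2_fold_changes=pd.DataFrame(
            {g: {grp: true_log2_fold_changes[g].get(grp, 0.0)
                 for grp in exp_groups} for g in targets}
        ).T.reindex(targets),
    )
    return CqTable(cq, table.metadata), truth
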