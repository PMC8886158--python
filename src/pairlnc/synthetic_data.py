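"""Synthetic cohorts with planted, recoverable signal.

Every input the analysis consumes can be simulated here: a multi-cell-type
immune expression panel with planted T-cell-specific lncRNAs, a tumor cohort
whose survival follows a Weibull-baseline proportional-hazards model driven
by planted lncRNA-pair indicators, lncRNA-miRNA-mRNA interaction tables with
planted complete triads plus decoy edges, and auxiliary gene-set /
infiltration / drug-IC50 tables with planted group differences.

All randomness flows from a single seed through named ``SeedSequence``
spawns, so identical configs produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import ExpressionMatrix

_CHECKPOINT_GENES = ["PDCD1_SYN", "CD274_SYN", "DNMT1_SYN", "ZC3H12D_SYN"]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Expression is generated directly on the log2(x+1) scale (no count
    model — the downstream pipeline is rank-based where it matters).
    Survival times follow a Weibull baseline hazard with scale/shape in
    months; censoring is independent exponential, calibrated so that the
    expected censored fraction matches ``censoring_fraction``.
    """

    seed: int = 0
    # immune panel ---------------------------------------------------------
    n_immune_celltypes: int = 4
    n_samples_per_type: int = 10
    n_lncrnas: int = 200
    n_specific: int = 15
    specific_logfc: float = 2.0
    noise_sd: float = 1.0
    n_batches: int = 1
    batch_effect_sd: float = 0.8
    # tumor cohort ---------------------------------------------------------
    n_patients: int = 300
    n_normals: int = 30
    planted_pairs: list[tuple[str, str, float]] | None = None
    planted_pair_prevalence: float = 0.5
    censoring_fraction: float = 0.3
    baseline_scale: float = 60.0
    baseline_shape: float = 1.2
    confound_clinical: bool = False
    # mRNA layer -----------------------------------------------------------
    n_mrnas: int = 400
    n_de_mrnas: int = 40
    mrna_logfc: float = 2.5
    immune_set_size: int = 25
    checkpoint_shift: float = 1.2
    # interactions ---------------------------------------------------------
    n_mirnas: int = 40
    n_planted_triads: int = 5
    n_decoy_edges: int = 30
    # auxiliary tables -----------------------------------------------------
    infiltration_rho: float = -0.5
    n_infiltration_celltypes: int = 6
    planted_drug_shift: float = 1.0
    n_null_drugs: int = 1

    def __post_init__(self):
        if self.n_immune_celltypes < 2:
            raise ValueError("need at least 2 immune cell types")
        if self.n_samples_per_type < 3:
            raise ValueError("need at least 3 samples per cell type")
        if self.n_specific > self.n_lncrnas:
            raise ValueError("n_specific cannot exceed n_lncrnas")
        if not 0.0 <= self.censoring_fraction <= 1.0:
            raise ValueError("censoring_fraction must be in [0, 1]")
        if min(self.baseline_scale, self.baseline_shape, self.noise_sd) <= 0:
            raise ValueError("scale, shape and noise_sd must be positive")
        if self.planted_pairs is None:
            spec = self.specific_lncrna_ids
            self.planted_pairs = []
            defaults = [0.8, -0.8, 0.6]
            for k, beta in enumerate(defaults):
                if 2 * k + 1 < len(spec):
                    self.planted_pairs.append((spec[2 * k], spec[2 * k + 1], beta))
        self.planted_pairs = [tuple(p) for p in self.planted_pairs]
        lnc_ids = set(self.lncrna_ids)
        for a, b, beta in self.planted_pairs:
            if a not in lnc_ids or b not in lnc_ids:
                raise ValueError(f"planted pair ({a}, {b}) references unknown lncRNA")
            if not np.isfinite(beta):
                raise ValueError("planted pair betas must be finite")

    # deterministic id universes ------------------------------------------
    @property
    def lncrna_ids(self) -> list[str]:
        return [f"LNC{i + 1:04d}" for i in range(self.n_lncrnas)]

    @property
    def specific_lncrna_ids(self) -> list[str]:
        return self.lncrna_ids[: self.n_specific]

    @property
    def mrna_ids(self) -> list[str]:
        return [f"MRNA{i + 1:04d}" for i in range(self.n_mrnas)]

    @property
    def de_mrna_ids(self) -> list[str]:
        return self.mrna_ids[: self.n_de_mrnas]

    @property
    def immune_set_ids(self) -> list[str]:
        return [f"IMM{i + 1:04d}" for i in range(self.immune_set_size)]

    @property
    def checkpoint_ids(self) -> list[str]:
        return list(_CHECKPOINT_GENES)

    @property
    def mirna_ids(self) -> list[str]:
        return [f"MIR{i + 1:04d}" for i in range(self.n_mirnas)]

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-keyed generator: independent streams, one master seed."""
        digest = int.from_bytes(stage.encode()[:4].ljust(4, b"\0"), "big")
        return np.random.default_rng(np.random.SeedSequence([self.seed, digest]))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_pairs"] = [list(p) for p in self.planted_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("planted_pairs") is not None:
            d["planted_pairs"] = [tuple(p) for p in d["planted_pairs"]]
        return cls(**d)


class ImmunePanel(NamedTuple):
    expr: ExpressionMatrix
    celltype: pd.Series       # "T" or "other_<k>"
    batch: pd.Series | None


class TumorCohort(NamedTuple):
    expr: ExpressionMatrix    # lncRNA + mRNA layers, tumor + normal samples
    survival: pd.DataFrame    # tumor samples only
    sample_type: pd.Series    # "tumor" / "normal"
    true_lp: pd.Series        # planted linear predictor per tumor sample
    truth: dict               # planted-signal bookkeeping


class InteractionTables(NamedTuple):
    lnc_mirna: pd.DataFrame
    mirna_mrna: list[pd.DataFrame]
    truth: dict


class AuxTables(NamedTuple):
    gene_sets: dict[str, list[str]]
    infiltration: pd.DataFrame
    ic50: pd.DataFrame
    truth: dict


# --------------------------------------------------------------------- panel

def generate_immune_panel(config: SimulationConfig) -> ImmunePanel:
    """Multi-cell-type lncRNA panel with T-cell-specific planted genes.

    The first ``n_specific`` lncRNAs get a +``specific_logfc`` mean shift in
    T-cell samples, so their expected logFC (T minus others) equals the
    configured effect size exactly.
    """
    rng = config.rng("panel")
    genes = config.lncrna_ids
    types = ["T"] + [f"other_{k}" for k in range(1, config.n_immune_celltypes)]
    samples, labels = [], []
    for ct in types:
        for j in range(config.n_samples_per_type):
            samples.append(f"{ct}_s{j + 1:02d}")
            labels.append("T" if ct == "T" else "other")
    base = rng.uniform(3.0, 9.0, size=len(genes))
    values = base[:, None] + rng.normal(0.0, config.noise_sd, (len(genes), len(samples)))
    is_t = np.array([lab == "T" for lab in labels])
    values[: config.n_specific, :] += config.specific_logfc * is_t[None, :]

    batch = None
    if config.n_batches > 1:
        assign = np.arange(len(samples)) % config.n_batches
        offsets = rng.normal(0.0, config.batch_effect_sd, (len(genes), config.n_batches))
        values += offsets[:, assign]
        batch = pd.Series([f"batch{b + 1}" for b in assign], index=samples, name="batch")

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        pd.Series("lncRNA", index=genes),
    )
    return ImmunePanel(expr, pd.Series(labels, index=samples, name="celltype"), batch)


# -------------------------------------------------------------------- cohort

def _pair_mean_offsets(config: SimulationConfig, rng) -> np.ndarray:
    """Per-lncRNA baseline means, with planted-pair prevalence control.

    For a planted pair (A, B) the indicator 1[expr_A > expr_B] under i.i.d.
    Gaussian noise has prevalence Phi((mu_A - mu_B) / (sqrt(2) * sd)), so the
    partner's mean is set to mu_B = mu_A - sqrt(2)*sd*Phi^-1(prevalence).
    """
    mu = rng.uniform(3.0, 9.0, size=config.n_lncrnas)
    delta = np.sqrt(2.0) * config.noise_sd * stats.norm.ppf(config.planted_pair_prevalence)
    idx = {g: i for i, g in enumerate(config.lncrna_ids)}
    for a, b, _beta in config.planted_pairs:
        mu[idx[b]] = mu[idx[a]] - delta
    return mu


def _calibrate_censoring_rate(latent_times: np.ndarray, target: float) -> float:
    """Exponential censoring rate r with mean(1 - exp(-r*T_i)) = target."""
    if target <= 0:
        return 0.0
    if target >= 1:
        return np.inf

    def deficit(log_r):
        return np.mean(1.0 - np.exp(-np.exp(log_r) * latent_times)) - target

    sol = optimize.brentq(deficit, -30.0, 30.0)
    return float(np.exp(sol))


def _draw_clinical(rng, n: int, lp: np.ndarray, confound: bool) -> pd.DataFrame:
    age = np.clip(np.round(rng.normal(61, 10, n)), 25, 90).astype(int)
    sex = rng.choice(["male", "female"], n, p=[0.7, 0.3])
    grade = rng.choice(["G1", "G2", "G3", "G4"], n, p=[0.10, 0.45, 0.35, 0.10])
    stage_p = np.tile([0.10, 0.15, 0.25, 0.50], (n, 1))
    if confound:
        # higher-risk patients skew toward later stage
        hi = lp > np.median(lp)
        stage_p[hi] = [0.05, 0.10, 0.20, 0.65]
    stage = np.array(
        [rng.choice(["I", "II", "III", "IV"], p=row) for row in stage_p]
    )
    t_stage = rng.choice(["T1", "T2", "T3", "T4"], n, p=[0.15, 0.30, 0.30, 0.25])
    n_stage = rng.choice(["N0", "N1", "N2"], n, p=[0.45, 0.25, 0.30])
    m_stage = rng.choice(["M0", "M1"], n, p=[0.95, 0.05])
    return pd.DataFrame(
        {"age": age, "sex": sex, "grade": grade, "stage": stage,
         "T": t_stage, "N": n_stage, "M": m_stage}
    )


def generate_tumor_cohort(config: SimulationConfig) -> TumorCohort:
    """Tumor cohort with proportional-hazards survival driven by pair indicators.

    Per patient the hazard is h(t) = h0(t) * exp(sum_k beta_k z_k) with h0 a
    Weibull(scale, shape) baseline and z_k the 0/1 indicator of planted pair
    k computed from the generated lncRNA expression itself. The expression
    matrix additionally carries an mRNA layer over tumor plus normal samples:
    planted tumor-vs-normal differential mRNAs, an immune gene-set module and
    four checkpoint-analogue genes whose expression rises as the true linear
    predictor falls (up-shifted in low-risk patients).
    """
    rng = config.rng("cohort")
    n, n_norm = config.n_patients, config.n_normals
    tumor_samples = [f"TUMOR{i + 1:04d}" for i in range(n)]
    normal_samples = [f"NORMAL{i + 1:04d}" for i in range(n_norm)]
    samples = tumor_samples + normal_samples

    # lncRNA layer (all cohort samples, so the panel intersection is full)
    mu = _pair_mean_offsets(config, rng)
    lnc = mu[:, None] + rng.normal(0.0, config.noise_sd, (config.n_lncrnas, len(samples)))
    lnc_df = pd.DataFrame(lnc, index=config.lncrna_ids, columns=samples)

    # planted pair indicators and true linear predictor (tumor samples)
    lp = np.zeros(n)
    z_truth = {}
    for a, b, beta in config.planted_pairs:
        z = (lnc_df.loc[a, tumor_samples].to_numpy()
             > lnc_df.loc[b, tumor_samples].to_numpy()).astype(int)
        z_truth[f"{a}|{b}"] = z
        lp += beta * z

    # Weibull proportional hazards: S(t) = exp(-(t/scale)^shape * e^lp)
    u = rng.uniform(size=n)
    latent = config.baseline_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / config.baseline_shape)
    latent = np.maximum(latent, 1e-6)
    if config.censoring_fraction > 0:
        rate = _calibrate_censoring_rate(latent, config.censoring_fraction)
        cens = rng.exponential(1.0 / rate, size=n) if np.isfinite(rate) else np.zeros(n)
        time = np.minimum(latent, cens)
        event = (latent <= cens).astype(int)
    else:
        time, event = latent, np.ones(n, dtype=int)
    if np.any(time <= 0):
        raise RuntimeError("generated non-positive survival time")

    clinical = _draw_clinical(rng, n, lp, config.confound_clinical)
    survival = pd.DataFrame({"time": np.round(time, 4), "event": event})
    survival = pd.concat([survival, clinical], axis=1)
    survival.index = pd.Index(tumor_samples, name="sample")

    # mRNA layer: plain mRNAs + immune module + checkpoint analogues
    mrna_genes = config.mrna_ids + config.immune_set_ids + config.checkpoint_ids
    base_m = rng.uniform(3.0, 9.0, size=len(mrna_genes))
    mvals = base_m[:, None] + rng.normal(0.0, config.noise_sd, (len(mrna_genes), len(samples)))
    mdf = pd.DataFrame(mvals, index=mrna_genes, columns=samples)
    # tumor-vs-normal differential mRNAs
    mdf.loc[config.de_mrna_ids, tumor_samples] += config.mrna_logfc
    # immune module + checkpoints track the negative of the risk predictor
    if n > 1 and np.std(lp) > 0:
        u_low = -(lp - lp.mean()) / lp.std()
    else:
        u_low = np.zeros(n)
    mdf.loc[config.immune_set_ids, tumor_samples] += 1.0 * u_low[None, :]
    mdf.loc[config.checkpoint_ids, tumor_samples] += config.checkpoint_shift * u_low[None, :]

    values = pd.concat([lnc_df, mdf])
    biotype = pd.Series("mRNA", index=values.index)
    biotype.loc[config.lncrna_ids] = "lncRNA"
    expr = ExpressionMatrix(values, biotype)

    sample_type = pd.Series(
        ["tumor"] * n + ["normal"] * n_norm, index=samples, name="sample_type"
    )
    truth = {
        "planted_pairs": [tuple(p) for p in config.planted_pairs],
        "pair_indicators": z_truth,
        "de_mrnas": config.de_mrna_ids,
        "immune_set": config.immune_set_ids,
        "checkpoints": config.checkpoint_ids,
    }
    return TumorCohort(
        expr, survival, sample_type,
        pd.Series(lp, index=tumor_samples, name="true_lp"), truth,
    )


# -------------------------------------------------------------- interactions

_TARGET_DBS = ("mirdb", "mirtarbase", "targetscan")


def generate_interaction_tables(config: SimulationConfig) -> InteractionTables:
    """lncRNA-miRNA and three miRNA-mRNA tables with planted complete triads.

    Each of the ``n_planted_triads`` chains lnc -> miRNA -> mRNA uses a
    T-cell-specific lncRNA and a planted tumor-differential mRNA, and the
    miRNA-mRNA edge appears in all three target tables. Decoy edges each
    break at least one condition of the consensus/hub rules: a target in
    only two of three tables, a non-differential consensus target, or a
    miRNA hanging off a non-specific lncRNA.
    """
    rng = config.rng("interactions")
    k = config.n_planted_triads
    if k > min(config.n_specific or 1, config.n_mirnas, config.n_de_mrnas) and k > 0:
        raise ValueError("not enough ids to plant the requested triads")

    lnc_mi: list[tuple[str, str, str]] = []
    mi_m: dict[str, list[tuple[str, str, str]]] = {db: [] for db in _TARGET_DBS}
    planted_mrnas, planted_mirnas, planted_lncs = [], [], []
    for i in range(k):
        lnc = config.specific_lncrna_ids[i % max(config.n_specific, 1)]
        mir = config.mirna_ids[i]
        mrna = config.de_mrna_ids[i]
        lnc_mi.append((lnc, mir, "mircode"))
        for db in _TARGET_DBS:
            mi_m[db].append((mir, mrna, db))
        planted_lncs.append(lnc)
        planted_mirnas.append(mir)
        planted_mrnas.append(mrna)

    non_de = [m for m in config.mrna_ids if m not in set(config.de_mrna_ids)]
    free_mirs = config.mirna_ids[k:] or config.mirna_ids
    nonspecific = config.lncrna_ids[config.n_specific:] or config.lncrna_ids
    for j in range(config.n_decoy_edges):
        kind = j % 3
        if kind == 0 and planted_mirnas:
            # consensus broken: target present in only 2 of 3 tables
            mir = planted_mirnas[j % len(planted_mirnas)]
            mrna = non_de[j % len(non_de)]
            for db in _TARGET_DBS[:2]:
                mi_m[db].append((mir, mrna, db))
        elif kind == 1 and planted_mirnas:
            # consensus target that is NOT differentially expressed -> no hub
            mir = planted_mirnas[j % len(planted_mirnas)]
            mrna = non_de[(j + 7) % len(non_de)]
            for db in _TARGET_DBS:
                mi_m[db].append((mir, mrna, db))
        else:
            # chain rooted at a non-specific lncRNA
            lnc = nonspecific[j % len(nonspecific)]
            mir = free_mirs[j % len(free_mirs)]
            mrna = config.mrna_ids[rng.integers(len(config.mrna_ids))]
            lnc_mi.append((lnc, mir, "mircode"))
            for db in _TARGET_DBS:
                mi_m[db].append((mir, mrna, db))

    cols = ["source_id", "target_id", "source_db"]
    lnc_table = pd.DataFrame(sorted(set(lnc_mi)), columns=cols)
    target_tables = [
        pd.DataFrame(sorted(set(mi_m[db])), columns=cols) for db in _TARGET_DBS
    ]
    truth = {
        "planted_mrnas": sorted(set(planted_mrnas)),
        "planted_mirnas": sorted(set(planted_mirnas)),
        "planted_lncs": sorted(set(planted_lncs)),
    }
    return InteractionTables(lnc_table, target_tables, truth)


# ----------------------------------------------------------------- auxiliary

def generate_auxiliary_tables(config: SimulationConfig, risk_proxy: pd.Series) -> AuxTables:
    """Gene sets, infiltration scores and IC50 tables keyed to the risk proxy.

    Infiltration scores target a Spearman correlation of
    ``infiltration_rho`` with the risk proxy via a Gaussian copula (Pearson
    r = 2*sin(rho*pi/6) on normal scores). Two drugs get opposite planted
    IC50 shifts between risk halves; ``n_null_drugs`` drugs carry no signal.
    """
    rng = config.rng("auxiliary")
    samples = list(risk_proxy.index)
    n = len(samples)

    gene_sets = {
        "IMMUNE_RESPONSE_SYNTH": list(config.immune_set_ids),
        "RANDOM_SET_SYNTH": list(config.mrna_ids[config.n_de_mrnas:
                                                 config.n_de_mrnas + 25]),
    }

    # normal scores of the risk ranks -> copula with the target Spearman rho
    ranks = stats.rankdata(risk_proxy.to_numpy(), method="average")
    u = stats.norm.ppf((ranks - 0.5) / n)
    r = 2.0 * np.sin(config.infiltration_rho * np.pi / 6.0)
    celltypes = ["T_cell_CD8", "T_cell_CD4", "B_cell", "NK_cell",
                 "Macrophage", "Dendritic_cell"][: config.n_infiltration_celltypes]
    inf = {
        ct: r * u + np.sqrt(max(0.0, 1 - r * r)) * rng.normal(size=n)
        for ct in celltypes
    }
    infiltration = pd.DataFrame(inf, index=pd.Index(samples, name="sample"))

    high = (risk_proxy.to_numpy() > np.median(risk_proxy.to_numpy())).astype(float)
    drugs = {
        # low-risk patients more sensitive (lower IC50 in low risk)
        "mitomycin_C_syn": rng.normal(size=n) + config.planted_drug_shift * high,
        # low-risk patients less sensitive
        "epothilone_B_syn": rng.normal(size=n) - config.planted_drug_shift * high,
    }
    for j in range(config.n_null_drugs):
        drugs[f"null_drug_{j + 1}"] = rng.normal(size=n)
    ic50 = pd.DataFrame(drugs, index=pd.Index(samples, name="sample"))

    truth = {
        "upshifted_set": "IMMUNE_RESPONSE_SYNTH",
        "null_set": "RANDOM_SET_SYNTH",
        "planted_drugs": ["mitomycin_C_syn", "epothilone_B_syn"],
        "null_drugs": [f"null_drug_{j + 1}" for j in range(config.n_null_drugs)],
    }
    return AuxTables(gene_sets, infiltration, ic50, truth)
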