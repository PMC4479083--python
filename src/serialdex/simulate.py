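"""Synthetic serial-biopsy cohort generator.

Emulates the statistical structure the downstream analyses assume, so the
whole pipeline is testable without clinical data:

* three biopsy time points per patient (T1, T2, TS) with incomplete pairing,
* print-batch additive offsets on the log2 scale,
* subtype structure generated from a nearest-centroid panel,
* treatment-induced downregulation of planted proliferation/immune genes at T2,
* a response-linked difference in early expression change (T2 - T1),
* recurrence hazards driven by planted genes in the residual tumor (TS).

The generative model, per patient p and gene g (all on the log2-ratio scale):

1. subtype ~ categorical(subtype_proportions); responder ~ Bernoulli(p_responder),
   then an RCB class consistent with the response label (a configurable
   fraction is recorded as "undetermined" to mimic missing pathology).
2. T1: x = centroid_effect_size * c(subtype, g) + eps, eps ~ N(0, sigma_noise^2);
   c is nonzero only for the panel genes.
3. T2 = T1 + shift, shift ~ N(mu, sigma_noise^2) with mu = -t2_downshift for
   proliferation/immune genes and mu = -response_delta_gap for response genes
   of (true) nonresponders, 0 otherwise.
4. TS (patients with residual disease, RCB I/II/III): TS = T1 + drift,
   drift ~ N(0, sigma_noise^2), plus a patient frailty f_p ~ N(0, frailty_sd^2)
   added to every hazard gene.
5. RFS: for patients with a residual tumor, event time ~ Exponential with
   rate = baseline_hazard * exp(hazard_beta * mean(TS expression of hazard
   genes)), censoring ~ Uniform(0, censor_time_max]; responders without
   residual disease are censored at censor_time_max.
6. Each sample is assigned a print batch uniformly; a batch x gene offset
   ~ N(0, batch_sd^2) is added to its values.  T2 samples of a configured
   fraction of patients and a fraction of TS samples are dropped.

Every random draw derives from a single seed through named
:class:`numpy.random.SeedSequence` sub-streams, so a fixed seed yields a
bit-identical cohort regardless of evaluation order.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CentroidPanel,
    ExpressionMatrix,
    has_residual_disease,
    validate_sample_meta,
)

_SUBSTREAMS = (
    "patient",
    "centroid",
    "batch",
    "t1",
    "shift",
    "ts",
    "survival",
    "missing",
    "probe",
)


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the serial-biopsy study design the package targets:
    48 patients with 25 % missing T2 biopsies gives exactly 36 T1-T2 pairs;
    the responder probability 0.21 reproduces the ~7:26 responder split of
    the evaluable pairs; six print batches; log2 noise sd 0.5 and batch sd
    0.3 are typical two-color microarray scales.  Planted gene sets are
    disjoint index ranges placed after the 50 centroid-panel genes.
    """

    n_patients: int = 48
    n_genes: int = 2000
    n_batches: int = 6
    subtype_labels: tuple[str, ...] = ("LumA", "LumB", "Her2", "Basal", "Normal")
    subtype_proportions: tuple[float, ...] = (0.35, 0.20, 0.15, 0.25, 0.05)
    n_centroid_genes: int = 50
    centroid_effect_size: float = 1.0
    sigma_noise: float = 0.5
    batch_sd: float = 0.3
    p_responder: float = 0.21
    frac_rcb_undetermined: float = 0.08
    frac_t2_missing: float = 0.25
    frac_ts_missing: float = 0.10
    prolif_genes: tuple[int, ...] = tuple(range(50, 150))
    immune_genes: tuple[int, ...] = tuple(range(150, 230))
    response_genes: tuple[int, ...] = tuple(range(230, 310))
    hazard_genes: tuple[int, ...] = tuple(range(310, 340))
    allow_overlap: bool = False
    t2_downshift: float = 0.5
    response_delta_gap: float = 0.8
    hazard_beta: float = 0.8
    frailty_sd: float = 3.0
    baseline_hazard: float = 0.02
    censor_time_max: float = 60.0
    probes_per_gene: int = 1
    probe_noise_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2 or self.n_genes < 1:
            raise ValueError("need >=2 patients and >=1 gene")
        if len(self.subtype_labels) != len(self.subtype_proportions):
            raise ValueError("subtype_labels and subtype_proportions length mismatch")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-8:
            raise ValueError("subtype_proportions must sum to 1")
        for name in ("sigma_noise", "batch_sd", "frailty_sd", "probe_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for frac in ("frac_t2_missing", "frac_ts_missing", "p_responder", "frac_rcb_undetermined"):
            if not 0 <= getattr(self, frac) <= 1:
                raise ValueError(f"{frac} must be in [0, 1]")
        planted = {
            "prolif_genes": self.prolif_genes,
            "immune_genes": self.immune_genes,
            "response_genes": self.response_genes,
            "hazard_genes": self.hazard_genes,
        }
        for name, idx in planted.items():
            arr = np.asarray(idx, dtype=int)
            if arr.size and (arr.min() < 0 or arr.max() >= self.n_genes):
                raise ValueError(f"{name} index out of range for n_genes={self.n_genes}")
        if not self.allow_overlap:
            all_idx = [i for idx in planted.values() for i in idx]
            if len(all_idx) != len(set(all_idx)):
                raise ValueError("planted gene sets overlap; set allow_overlap=True to permit")

    def null(self) -> "SimConfig":
        """The same design with every planted signal switched off."""
        return dataclasses.replace(self, t2_downshift=0.0, response_delta_gap=0.0, hazard_beta=0.0)


@dataclasses.dataclass
class CohortTruth:
    """Ground truth of a simulated cohort: planted memberships and parameters."""

    config: SimConfig
    gene_ids: list[str]
    prolif_genes: list[str]
    immune_genes: list[str]
    response_genes: list[str]
    hazard_genes: list[str]
    subtype: dict[str, str]          # patient -> generating subtype
    responder: dict[str, bool]       # patient -> true response label
    frailty: dict[str, float]        # patient -> TS frailty
    centroid_panel: CentroidPanel
    probe_to_gene: dict[str, str] | None = None

    @property
    def t2_shift_genes(self) -> list[str]:
        """Genes with a planted T2 downshift (proliferation + immune)."""
        return self.prolif_genes + self.immune_genes

    @property
    def t2_marginal_shift_genes(self) -> list[str]:
        """All genes whose marginal T2 - T1 mean is shifted.

        Besides the proliferation/immune downshift, the response-linked
        planting moves nonresponders only; with unequal group sizes that
        also shifts the marginal mean, so response genes are genuinely
        differentially expressed in the paired T1 vs T2 contrast and belong
        to its truth set.
        """
        out: list[str] = []
        if self.config.t2_downshift != 0:
            out += self.prolif_genes + self.immune_genes
        if self.config.response_delta_gap != 0:
            out += self.response_genes
        return out

    def to_dict(self) -> dict:
        return {
            "config": dataclasses.asdict(self.config),
            "prolif_genes": self.prolif_genes,
            "immune_genes": self.immune_genes,
            "response_genes": self.response_genes,
            "hazard_genes": self.hazard_genes,
            "subtype": self.subtype,
            "responder": self.responder,
            "frailty": self.frailty,
        }


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_cohort(config: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame, CohortTruth]:
    """Draw one cohort from the generative model described in the module docstring.

    Returns the expression matrix (gene level, or probe level when
    ``probes_per_gene > 1``), the validated sample sheet, and the
    :class:`CohortTruth` record of planted memberships and parameters.
    """
    config.validate()
    streams = {
        name: np.random.default_rng(ss)
        for name, ss in zip(_SUBSTREAMS, np.random.SeedSequence(config.seed).spawn(len(_SUBSTREAMS)))
    }

    n_pat, n_genes = config.n_patients, config.n_genes
    genes = _gene_ids(n_genes)
    patients = [f"P{i:03d}" for i in range(n_pat)]

    rng = streams["patient"]
    subtype_idx = rng.choice(len(config.subtype_labels), size=n_pat, p=config.subtype_proportions)
    responder = rng.random(n_pat) < config.p_responder
    # RCB class consistent with the response label: responders are mostly RCB 0
    # with occasional RCB I; nonresponders split II vs III.
    rcb = np.where(
        responder,
        np.where(rng.random(n_pat) < 6 / 7, "0", "I"),
        np.where(rng.random(n_pat) < 0.6, "II", "III"),
    ).astype(object)
    undetermined = rng.random(n_pat) < config.frac_rcb_undetermined
    rcb[undetermined] = "undetermined"
    # HR status loosely tracks subtype (luminal mostly positive).
    p_hr = np.select(
        [subtype_idx <= 1, subtype_idx == len(config.subtype_labels) - 1],
        [0.90, 0.50],
        default=0.15,
    )
    hr_status = np.where(rng.random(n_pat) < p_hr, "positive", "negative")

    # Centroid panel over the first n_centroid_genes genes.
    n_cg = min(config.n_centroid_genes, n_genes)
    centroids = pd.DataFrame(
        streams["centroid"].standard_normal((n_cg, len(config.subtype_labels))),
        index=genes[:n_cg],
        columns=list(config.subtype_labels),
    )
    panel = CentroidPanel(centroids)

    # T1 biology: subtype centroid signal + iid noise.
    t1 = streams["t1"].standard_normal((n_genes, n_pat)) * config.sigma_noise
    t1[:n_cg, :] += config.centroid_effect_size * centroids.to_numpy()[:, subtype_idx]

    # T2 = T1 + shift.
    shift_mu = np.zeros((n_genes, n_pat))
    planted_shift = list(config.prolif_genes) + list(config.immune_genes)
    if planted_shift:
        shift_mu[np.asarray(planted_shift, dtype=int), :] -= config.t2_downshift
    if len(config.response_genes):
        resp_idx = np.asarray(config.response_genes, dtype=int)
        shift_mu[np.ix_(resp_idx, ~responder)] -= config.response_delta_gap
    t2 = t1 + shift_mu + streams["shift"].standard_normal((n_genes, n_pat)) * config.sigma_noise

    # TS = T1 + drift (+ frailty on hazard genes); generated for residual disease.
    rng_ts = streams["ts"]
    frailty = rng_ts.standard_normal(n_pat) * config.frailty_sd
    ts = t1 + rng_ts.standard_normal((n_genes, n_pat)) * config.sigma_noise
    if len(config.hazard_genes):
        haz_idx = np.asarray(config.hazard_genes, dtype=int)
        ts[haz_idx, :] += frailty[None, :]
    has_ts = np.array([has_residual_disease(r) for r in rcb])

    # RFS from the realized TS values of the hazard genes.
    rng_surv = streams["survival"]
    rfs_time = np.full(n_pat, config.censor_time_max, dtype=float)
    rfs_event = np.zeros(n_pat, dtype=int)
    if len(config.hazard_genes):
        score = ts[np.asarray(config.hazard_genes, dtype=int), :].mean(axis=0)
    else:
        score = np.zeros(n_pat)
    rate = config.baseline_hazard * np.exp(config.hazard_beta * score)
    event_time = rng_surv.exponential(1.0 / rate)
    censor_time = rng_surv.uniform(0.0, config.censor_time_max, size=n_pat)
    censor_time = np.nextafter(censor_time, config.censor_time_max)  # open at 0
    obs = np.minimum(event_time, censor_time)
    rfs_time[has_ts] = obs[has_ts]
    rfs_event[has_ts] = (event_time <= censor_time)[has_ts].astype(int)

    # Missing follow-up biopsies: drop a fixed count of T2 and TS samples.
    rng_miss = streams["missing"]
    n_t2_drop = int(round(config.frac_t2_missing * n_pat))
    t2_dropped = set(rng_miss.choice(n_pat, size=n_t2_drop, replace=False).tolist())
    ts_candidates = np.flatnonzero(has_ts)
    n_ts_drop = int(round(config.frac_ts_missing * len(ts_candidates)))
    ts_dropped = (
        set(rng_miss.choice(ts_candidates, size=n_ts_drop, replace=False).tolist())
        if n_ts_drop
        else set()
    )

    sample_rows = []
    columns: list[np.ndarray] = []
    for p in range(n_pat):
        sample_rows.append((p, "T1", t1[:, p]))
        if p not in t2_dropped:
            sample_rows.append((p, "T2", t2[:, p]))
        if has_ts[p] and p not in ts_dropped:
            sample_rows.append((p, "TS", ts[:, p]))

    rng_batch = streams["batch"]
    batch_offsets = rng_batch.standard_normal((config.n_batches, n_genes)) * config.batch_sd
    batches = rng_batch.integers(0, config.n_batches, size=len(sample_rows))

    sample_ids, meta_rows = [], []
    for (p, tp, vec), b in zip(sample_rows, batches):
        sid = f"{patients[p]}_{tp}"
        sample_ids.append(sid)
        columns.append(vec + batch_offsets[b])
        meta_rows.append(
            {
                "sample_id": sid,
                "patient_id": patients[p],
                "timepoint": tp,
                "batch": f"B{b + 1}",
                "rcb": rcb[p] if rcb[p] != "undetermined" else "undetermined",
                "hr_status": hr_status[p],
                "rfs_time": rfs_time[p],
                "rfs_event": rfs_event[p],
            }
        )

    values = pd.DataFrame(np.column_stack(columns), index=genes, columns=sample_ids)
    meta = validate_sample_meta(pd.DataFrame(meta_rows))

    probe_to_gene = None
    level = "gene"
    if config.probes_per_gene > 1:
        k = config.probes_per_gene
        probe_ids = [f"{g}_PR{j + 1}" for g in genes for j in range(k)]
        expanded = np.repeat(values.to_numpy(), k, axis=0)
        expanded = expanded + streams["probe"].standard_normal(expanded.shape) * config.probe_noise_sd
        values = pd.DataFrame(expanded, index=probe_ids, columns=sample_ids)
        probe_to_gene = {pid: pid.rsplit("_PR", 1)[0] for pid in probe_ids}
        level = "probe"

    def _named(idx: Sequence[int]) -> list[str]:
        return [genes[i] for i in idx]

    truth = CohortTruth(
        config=config,
        gene_ids=genes,
        prolif_genes=_named(config.prolif_genes),
        immune_genes=_named(config.immune_genes),
        response_genes=_named(config.response_genes),
        hazard_genes=_named(config.hazard_genes),
        subtype={patients[p]: config.subtype_labels[subtype_idx[p]] for p in range(n_pat)},
        responder={patients[p]: bool(responder[p]) for p in range(n_pat)},
        frailty={patients[p]: float(frailty[p]) for p in range(n_pat)},
        centroid_panel=panel,
        probe_to_gene=probe_to_gene,
    )
    return ExpressionMatrix(values, level=level), meta, truth


def truth_eval(called, planted, universe) -> tuple[float, float]:
    """Sensitivity and observed false-discovery proportion of a called set.

    ``sensitivity = |planted ∩ called| / |planted|``;
    ``observed FDR = |called \\ planted| / |called|`` (0 when nothing is
    called).  ``called`` and ``planted`` must lie within ``universe``;
    a mismatched gene universe is an error.
    """
    called = set(called)
    planted = set(planted)
    universe = set(universe)
    if not planted:
        raise ValueError("planted set is empty")
    if not called <= universe:
        raise ValueError("called features outside the gene universe")
    if not planted <= universe:
        raise ValueError("planted features outside the gene universe")
    sensitivity = len(planted & called) / len(planted)
    fdr = len(called - planted) / len(called) if called else 0.0
    return sensitivity, fdr
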