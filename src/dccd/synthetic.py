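"""Synthetic cohorts with planted ground truth.

Every downstream stage of the pipeline (marker extraction, consensus
subtyping, NTP classification, DCCD scoring, metabolite DA, survival) is
exercised on data generated here, so recovery of the planted structure can
be asserted without any external download.

Generators are pure functions of their arguments including the seed; each
draws from its own deterministic sub-stream of the global seed so stages
can be re-run independently.

Model choices
-------------
* Single-cell counts: negative binomial with mean ``m`` and dispersion
  ``phi`` (variance ``m + phi * m**2``); baseline gene means are log-normal.
  Cluster markers get a multiplicative ``2**marker_log2fc`` shift.
* Bulk expression: additive model in log2 space — baseline + subtype
  signature boost + Gaussian noise — exported as linear TPM.  With the
  DCCD gradient on, IM1/IM3 samples blend the IM2 and IM4 signatures by a
  uniform mixing fraction (IM2 samples sit at 0, IM4 at 1).
* Survival: exponential times with subtype-specific hazards and
  independent uniform censoring.
* Metabolome: log-normal intensities with planted up/down pathway shifts
  in the tumor group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CellTable, ExpressionMatrix, GeneSetCollection

# sub-stream tags so each generator gets an independent deterministic RNG
_STREAM_SC = 11
_STREAM_BULK = 22
_STREAM_METAB = 33
_STREAM_MIXTURE = 44

#: Default per-day hazards.  IM4 is the poor-prognosis DCCD subtype with a
#: hazard ratio of 3 versus IM2 (median survival ~277 vs ~832 days).
DEFAULT_HAZARDS = {"IM1": 1 / 800.0, "IM2": 1 / 1200.0,
                   "IM3": 1 / 800.0, "IM4": 1 / 400.0}


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside every simulated dataset."""

    seed: int
    cell_cluster_labels: pd.Series | None = None
    planted_markers: dict[str, dict[str, float]] = field(default_factory=dict)
    bulk_subtype_labels: pd.Series | None = None
    dccd_mixing_fraction: pd.Series | None = None
    metabolite_shifts: dict[str, dict] = field(default_factory=dict)
    hazard_by_subtype: dict[str, float] = field(default_factory=dict)
    group_labels: pd.Series | None = None
    expected_da_score: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dccd_mixing_fraction is not None:
            m = self.dccd_mixing_fraction
            if ((m < 0) | (m > 1)).any():
                raise ValueError("mixing fractions must lie in [0, 1]")
        if any(h <= 0 for h in self.hazard_by_subtype.values()):
            raise ValueError("hazards must be positive")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def simulate_sc_counts(
    n_cells: int = 2000,
    clusters: list[tuple[str, float]] | None = None,
    n_genes: int = 1200,
    markers_per_cluster: int = 40,
    marker_log2fc: float = 2.0,
    nb_dispersion: float = 0.3,
    seed: int = 0,
    n_samples: int = 4,
) -> tuple[CellTable, SyntheticTruth]:
    """Simulate a labeled single-cell UMI count matrix with planted markers.

    Cells are assigned to clusters by the given proportions; each cluster
    owns ``markers_per_cluster`` disjoint marker genes whose negative
    binomial mean is multiplied by ``2**marker_log2fc`` inside the cluster.
    Cells are also spread round-robin over ``n_samples`` samples of origin.
    """
    if clusters is None:
        clusters = [(f"C{i + 1}", 1.0 / 4) for i in range(4)]
    names = [c[0] for c in clusters]
    props = np.array([c[1] for c in clusters], float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("cluster proportions must sum to 1")
    if markers_per_cluster * len(clusters) > n_genes:
        raise ValueError("marker budget exceeds n_genes")
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")

    rng = _rng(seed, _STREAM_SC)
    counts_per_cluster = np.floor(props * n_cells).astype(int)
    counts_per_cluster[0] += n_cells - counts_per_cluster.sum()
    labels = np.repeat(names, counts_per_cluster)

    genes = [f"g{i:05d}" for i in range(n_genes)]
    base_mean = rng.lognormal(mean=1.0, sigma=1.0, size=n_genes)

    planted: dict[str, dict[str, float]] = {}
    mean_matrix = np.tile(base_mean[:, None], (1, len(names)))
    gi = 0
    for ci, name in enumerate(names):
        idx = np.arange(gi, gi + markers_per_cluster)
        gi += markers_per_cluster
        mean_matrix[idx, ci] *= 2.0 ** marker_log2fc
        planted[name] = {genes[i]: marker_log2fc for i in idx}

    cluster_idx = np.repeat(np.arange(len(names)), counts_per_cluster)
    means = mean_matrix[:, cluster_idx]  # genes x cells
    n_nb = 1.0 / nb_dispersion
    p_nb = n_nb / (n_nb + means)
    counts = rng.negative_binomial(n_nb, p_nb)

    cells = [f"cell{i:05d}" for i in range(n_cells)]
    df = pd.DataFrame(counts, index=genes, columns=cells, dtype=float)
    cluster_label = pd.Series(labels, index=cells, name="cluster")
    sample = pd.Series([f"S{i % n_samples + 1}" for i in range(n_cells)],
                       index=cells, name="sample_of_origin")
    table = CellTable(ExpressionMatrix(df, "counts"), cluster_label, sample)
    truth = SyntheticTruth(seed=seed, cell_cluster_labels=cluster_label,
                           planted_markers=planted)
    return table, truth


def default_bulk_signatures(genes_per_subtype: int = 40,
                            n_genes: int = 800) -> GeneSetCollection:
    """Disjoint per-subtype signature gene sets over a synthetic gene space."""
    if 4 * genes_per_subtype > n_genes:
        raise ValueError("signature budget exceeds n_genes")
    sets = {}
    for si, name in enumerate(("IM1", "IM2", "IM3", "IM4")):
        lo = si * genes_per_subtype
        sets[name] = [f"b{i:05d}" for i in range(lo, lo + genes_per_subtype)]
    return GeneSetCollection(sets)


def simulate_bulk_cohort(
    n_samples: int = 120,
    subtype_proportions: dict[str, float] | None = None,
    signatures: GeneSetCollection | None = None,
    signature_log2fc: float = 2.0,
    noise_sd: float = 1.0,
    dccd_gradient: bool = False,
    seed: int = 0,
    n_genes: int = 800,
    hazard_by_subtype: dict[str, float] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate a bulk TPM cohort with four planted subtypes and survival.

    log2 TPM = per-gene baseline + ``signature_log2fc`` on the sample's own
    subtype signature + N(0, noise_sd).  With ``dccd_gradient``, every
    sample carries a mixing fraction m (IM2 = 0, IM4 = 1, IM1/IM3 ~ U(0,1))
    adding ``(1-m)*log2fc`` on the IM2 signature and ``m*log2fc`` on the
    IM4 signature.  Survival times are exponential with per-subtype hazards
    and independently uniformly censored on (0, 3 x max mean survival).
    """
    if subtype_proportions is None:
        subtype_proportions = {s: 0.25 for s in ("IM1", "IM2", "IM3", "IM4")}
    if abs(sum(subtype_proportions.values()) - 1.0) > 1e-9:
        raise ValueError("subtype proportions must sum to 1")
    if signatures is None:
        signatures = default_bulk_signatures(n_genes=n_genes)
    if hazard_by_subtype is None:
        hazard_by_subtype = dict(DEFAULT_HAZARDS)

    rng = _rng(seed, _STREAM_BULK)
    subtypes = sorted(subtype_proportions)
    counts = np.floor(np.array([subtype_proportions[s] for s in subtypes])
                      * n_samples).astype(int)
    counts[0] += n_samples - counts.sum()
    labels = np.repeat(subtypes, counts)
    rng.shuffle(labels)

    sig_union = signatures.union()
    extra = [f"n{i:05d}" for i in range(max(0, n_genes - len(sig_union)))]
    genes = sig_union + extra
    gene_pos = {g: i for i, g in enumerate(genes)}
    baseline = rng.normal(loc=3.0, scale=1.0, size=len(genes))

    mixing = np.zeros(n_samples)
    log2x = np.tile(baseline[:, None], (1, n_samples))
    for j, lab in enumerate(labels):
        if lab in signatures.sets:
            own = [gene_pos[g] for g in signatures[lab] if g in gene_pos]
            log2x[own, j] += signature_log2fc
        if dccd_gradient:
            if lab == "IM2":
                m = 0.0
            elif lab == "IM4":
                m = 1.0
            else:
                m = float(rng.uniform())
            mixing[j] = m
            if lab in ("IM1", "IM3"):
                im2 = [gene_pos[g] for g in signatures["IM2"] if g in gene_pos]
                im4 = [gene_pos[g] for g in signatures["IM4"] if g in gene_pos]
                log2x[im2, j] += (1.0 - m) * signature_log2fc
                log2x[im4, j] += m * signature_log2fc
    if noise_sd > 0:
        log2x += rng.normal(scale=noise_sd, size=log2x.shape)

    sample_ids = [f"B{j:04d}" for j in range(n_samples)]
    tpm = pd.DataFrame(2.0 ** log2x, index=genes, columns=sample_ids)
    expr = ExpressionMatrix(tpm, "tpm")

    hazards = np.array([hazard_by_subtype[s] for s in labels])
    t_event = rng.exponential(1.0 / hazards)
    cens_hi = 3.0 * max(1.0 / h for h in hazard_by_subtype.values())
    t_cens = rng.uniform(0, cens_hi, size=n_samples)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)
    meta = pd.DataFrame({
        "sample_id": sample_ids,
        "group": "tumor",
        "stage": "NA",
        "grade": "NA",
        "os_time": os_time,
        "os_event": os_event,
    }).set_index("sample_id")

    truth = SyntheticTruth(
        seed=seed,
        bulk_subtype_labels=pd.Series(labels, index=sample_ids, name="subtype"),
        dccd_mixing_fraction=pd.Series(mixing, index=sample_ids, name="mixing"),
        planted_markers={s: {g: signature_log2fc for g in signatures[s]}
                         for s in signatures},
        hazard_by_subtype=dict(hazard_by_subtype),
    )
    return expr, meta, truth


def simulate_metabolome(
    n_samples_per_group: int = 20,
    pathways: dict[str, list[str]] | None = None,
    shifts: dict[str, tuple[int, int, float]] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate tumor-vs-normal metabolite intensities with planted shifts.

    Intensities are log-normal; within each shifted pathway the first
    ``n_up`` metabolites gain ``+log2_effect`` and the next ``n_down`` lose
    ``log2_effect`` (log2 scale) in the tumor group.  The truth records the
    DA score each pathway is designed to produce,
    ``(n_up - n_down) / n_measured``.
    """
    if pathways is None:
        pathways = {f"pw{k}": [f"m{k}_{i}" for i in range(10)] for k in range(5)}
    if shifts is None:
        shifts = {}
    rng = _rng(seed, _STREAM_METAB)

    metabolites: list[str] = []
    for members in pathways.values():
        for m in members:
            if m not in metabolites:
                metabolites.append(m)
    n_met = len(metabolites)
    pos = {m: i for i, m in enumerate(metabolites)}

    n = n_samples_per_group
    samples = [f"T{i:03d}" for i in range(n)] + [f"N{i:03d}" for i in range(n)]
    groups = pd.Series(["tumor"] * n + ["normal"] * n, index=samples, name="group")

    base = rng.normal(loc=10.0, scale=1.0, size=n_met)
    log2x = np.tile(base[:, None], (1, 2 * n))
    truth_shifts: dict[str, dict] = {}
    expected: dict[str, float] = {}
    for pw, (n_up, n_down, eff) in shifts.items():
        members = pathways[pw]
        if n_up + n_down > len(members):
            raise ValueError(f"pathway {pw!r}: n_up + n_down exceeds pathway size")
        up = members[:n_up]
        down = members[n_up:n_up + n_down]
        for m in up:
            log2x[pos[m], :n] += eff
        for m in down:
            log2x[pos[m], :n] -= eff
        truth_shifts[pw] = {"n_up": n_up, "n_down": n_down, "effect": eff,
                            "up": up, "down": down}
        expected[pw] = (n_up - n_down) / len(members) if eff != 0 else 0.0
    for pw in pathways:
        expected.setdefault(pw, 0.0)
    if noise_sd > 0:
        log2x += rng.normal(scale=noise_sd, size=log2x.shape)

    expr = ExpressionMatrix(
        pd.DataFrame(2.0 ** log2x, index=metabolites, columns=samples),
        "intensity")
    truth = SyntheticTruth(seed=seed, metabolite_shifts=truth_shifts,
                           group_labels=groups, expected_da_score=expected)
    return expr, truth


def simulate_dccd_cells(
    n_samples: int = 10,
    cells_per_sample: int = 300,
    im4_fractions: np.ndarray | None = None,
    n_genes: int = 600,
    markers_per_archetype: int = 40,
    marker_log2fc: float = 2.0,
    nb_dispersion: float = 0.3,
    seed: int = 0,
) -> tuple[CellTable, SyntheticTruth]:
    """Malignant-cell mixtures of the IM2 and IM4 archetypes.

    Each sample is a planted mixture: a fraction of its cells carry the
    IM4-archetype marker boost, the rest the IM2-archetype boost.  Used to
    test cell-level DCCD scoring and its per-sample IM4-like fraction
    against pseudobulk scores.
    """
    rng = _rng(seed, _STREAM_MIXTURE)
    if im4_fractions is None:
        im4_fractions = np.linspace(0.1, 0.9, n_samples)
    im4_fractions = np.asarray(im4_fractions, float)
    if len(im4_fractions) != n_samples:
        raise ValueError("need one IM4 fraction per sample")
    if 2 * markers_per_archetype > n_genes:
        raise ValueError("marker budget exceeds n_genes")

    genes = [f"g{i:05d}" for i in range(n_genes)]
    base_mean = rng.lognormal(mean=1.0, sigma=1.0, size=n_genes)
    im2_idx = np.arange(markers_per_archetype)
    im4_idx = np.arange(markers_per_archetype, 2 * markers_per_archetype)

    all_counts, labels, origin, cells = [], [], [], []
    n_nb = 1.0 / nb_dispersion
    for s in range(n_samples):
        n4 = int(round(im4_fractions[s] * cells_per_sample))
        arch = np.array(["IM4-arch"] * n4
                        + ["IM2-arch"] * (cells_per_sample - n4))
        means = np.tile(base_mean[:, None], (1, cells_per_sample))
        means[np.ix_(im4_idx, np.where(arch == "IM4-arch")[0])] *= 2.0 ** marker_log2fc
        means[np.ix_(im2_idx, np.where(arch == "IM2-arch")[0])] *= 2.0 ** marker_log2fc
        p_nb = n_nb / (n_nb + means)
        all_counts.append(rng.negative_binomial(n_nb, p_nb))
        labels.extend(arch)
        origin.extend([f"P{s + 1}"] * cells_per_sample)
        cells.extend(f"P{s + 1}_c{i:04d}" for i in range(cells_per_sample))

    df = pd.DataFrame(np.concatenate(all_counts, axis=1),
                      index=genes, columns=cells, dtype=float)
    table = CellTable(ExpressionMatrix(df, "counts"),
                      pd.Series(labels, index=cells, name="cluster"),
                      pd.Series(origin, index=cells, name="sample_of_origin"))
    truth = SyntheticTruth(
        seed=seed,
        cell_cluster_labels=table.cluster_label,
        planted_markers={
            "IM2-arch": {genes[i]: marker_log2fc for i in im2_idx},
            "IM4-arch": {genes[i]: marker_log2fc for i in im4_idx},
        },
        dccd_mixing_fraction=pd.Series(im4_fractions,
                                       index=[f"P{s + 1}" for s in range(n_samples)]),
    )
    return table, truth


def planted_overlap_markers(n_clusters: int = 25, top_n: int = 60,
                            union_size: int = 911) -> pd.DataFrame:
    """Marker table whose per-cluster top-``top_n`` lists union to ``union_size`` genes.

    Deterministic construction emulating the situation where 25 cell
    subpopulations each contribute their top 60 markers but shared markers
    collapse the union (25 x 60 = 1,500 slots over 911 distinct genes).
    Every gene appears in at least one cluster; every cluster holds exactly
    ``top_n`` distinct genes, all passing the default candidate cutoffs.
    """
    slots = n_clusters * top_n
    if not (n_clusters <= union_size <= slots):
        raise ValueError("need n_clusters <= union_size <= n_clusters * top_n")
    genes = [f"mk{i:04d}" for i in range(union_size)]
    assigned: list[list[str]] = [[] for _ in range(n_clusters)]
    # first pass: spread every distinct gene round-robin so all are used
    for i, g in enumerate(genes):
        assigned[i % n_clusters].append(g)
    # second pass: top up each cluster to top_n by borrowing other genes
    cursor = 0
    for c in range(n_clusters):
        have = set(assigned[c])
        while len(assigned[c]) < top_n:
            g = genes[cursor % union_size]
            cursor += 1
            if g not in have:
                assigned[c].append(g)
                have.add(g)
    rows = []
    for c, members in enumerate(assigned):
        for r, g in enumerate(members):
            rows.append({
                "gene": g,
                "cluster": f"C{c + 1:02d}",
                "log2fc": 4.0 - r * (2.0 / top_n),  # descending, all > 1
                "p_value": 1e-12,
                "p_adj": 1e-10,
                "rank_in_cluster": r + 1,
            })
    return pd.DataFrame(rows)
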