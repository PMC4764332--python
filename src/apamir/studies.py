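"""End-to-end validation studies on synthetic cohorts.

These functions drive the whole pipeline on generated data and summarize
how well it recovers the planted structure: cleavage-site recovery, null
calibration of the positional tests, detection power for the planted
5'-of-APA enrichment, agreement of the score comparison with closed-form
statistics, and codon-usage class recovery. They are the package's own
validation battery; the test suite and the reproduction script both call
them.

Study sizes: recovery runs the full read-level pipeline at the default
1,000-gene scale; calibration and power use positional cohorts of 17,500
genes, sized so the flank-filtered two-class union (~365 genes) matches
the scale of a genome-wide two-set contrast, with 50 cohorts of 1,000
randomization iterations each.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from apamir import genesets, positional_stats as ps, site_mapping
from apamir.apa_assignment import assign_cs_to_utrs, filter_flank
from apamir.cs_calling import call_cleavage_sites
from apamir.site_mapping import SeedSite
from apamir.synthetic_data import (
    CLASS_PRODIFF,
    CLASS_PROPROLIF,
    SimConfig,
    plan_cohort,
    positional_view,
    simulate,
    truth_report,
)

CAL_N_GENES = 17_500
CAL_N_COHORTS = 50
CAL_N_ITER = 1_000
WINDOW_BINS = slice(7, 10)  # [-300, 0) at flank 1000 / bin width 100


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Child seeds below 2**31, deterministic in ``seed``."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def pipeline_recovery_study(seed: int, n_genes: int = 1000) -> dict:
    """Full read-level pipeline on one default-condition cohort."""
    cfg = SimConfig(n_genes=n_genes, seed=int(seed))
    bundle = simulate(cfg)
    sites = call_cleavage_sites(bundle.read_ends, bundle.genome)
    calls = assign_cs_to_utrs(sites, bundle.utrs)
    rep = truth_report(bundle.truth, sites, calls)
    found = site_mapping.scan_all(bundle.utrs, bundle.seeds)
    mismatch = site_mapping.label_conserved(found, bundle.conserved_table,
                                            bundle.utrs, bundle.seeds)
    rep.update({
        "n_sites_called_total": float(len(sites)),
        "n_internal_priming_flagged": float(
            sum(s.internal_priming for s in sites)),
        "n_apa_positive_genes": float(
            sum(c.is_apa_positive for c in calls)),
        "n_seed_sites_scanned": float(len(found)),
        "conserved_table_mismatch_rate": float(mismatch),
    })
    return rep


def _no_signal_cfg(n_genes: int, seed: int) -> SimConfig:
    return SimConfig(n_genes=n_genes, enrichment_factor=1.0,
                     distal_enrichment_factor=1.0, seed=int(seed))


def calibration_study(seed: int, n_cohorts: int = CAL_N_COHORTS,
                      n_genes: int = CAL_N_GENES,
                      n_iter: int = CAL_N_ITER) -> dict:
    """Null calibration of the three positional tests.

    Cohorts are generated with no positional structure; per-bin randomized
    (tie-broken) p-values are pooled over cohorts and compared with
    Uniform(0,1) by a KS test. Fractions of deterministic p-values below
    0.05 are reported alongside (they run conservative by construction).
    """
    seeds = _spawn_seeds(seed, 2 * n_cohorts)
    pooled: dict[str, list[np.ndarray]] = {
        "apa_null": [], "two_set": [], "cluster": []}
    pooled_det: dict[str, list[np.ndarray]] = {
        "apa_null": [], "two_set": [], "cluster": []}
    for i in range(n_cohorts):
        truth = plan_cohort(_no_signal_cfg(n_genes, seeds[i]))
        calls, sites = positional_view(truth)
        kept = filter_flank(calls, ps.DEFAULT_FLANK)
        it_seed = int(seeds[n_cohorts + i])
        ens = ps.randomized_apa_null(kept, sites, n_iter=n_iter,
                                     seed=it_seed)
        pooled["apa_null"].append(ens.p_values_randomized)
        pooled_det["apa_null"].append(ens.p_values)
        r = ps.two_set_partition_test(
            truth.class_members(CLASS_PROPROLIF),
            truth.class_members(CLASS_PRODIFF),
            kept, sites, n_iter=n_iter, seed=it_seed)
        pooled["two_set"].append(r.p_values_randomized)
        pooled_det["two_set"].append(r.p_values)
        rc = ps.cluster_vs_all_test(truth.cluster_families, kept, sites,
                                    n_iter=n_iter, seed=it_seed)
        pooled["cluster"].append(rc.p_values_randomized)
        pooled_det["cluster"].append(rc.p_values)
    out: dict[str, float] = {"n_cohorts": float(n_cohorts)}
    for name in pooled:
        pv = np.concatenate(pooled[name])
        det = np.concatenate(pooled_det[name])
        out[f"ks_p_{name}"] = float(stats.kstest(pv, "uniform").pvalue)
        out[f"frac_below_05_{name}"] = float((det < 0.05).mean())
    return out


def power_study(seed: int, n_cohorts: int = CAL_N_COHORTS,
                n_genes: int = CAL_N_GENES,
                n_iter: int = CAL_N_ITER) -> dict:
    """Detection power for the planted 5'-of-APA enrichment.

    Default generator conditions (3x conserved-site density in the 300 nt
    5' of the proximal APA site, enriched class only). A cohort counts as
    detected when every [-300, 0) bin reaches p < 0.05 — for the two-set
    partition test (enriched vs other class) and for the randomized-anchor
    null over the enriched class's genes.
    """
    seeds = _spawn_seeds(seed + 1, 2 * n_cohorts)
    hits_two_set = hits_apa_null = 0
    for i in range(n_cohorts):
        cfg = SimConfig(n_genes=n_genes, seed=int(seeds[i]))
        truth = plan_cohort(cfg)
        calls, sites = positional_view(truth)
        kept = filter_flank(calls, ps.DEFAULT_FLANK)
        it_seed = int(seeds[n_cohorts + i])
        r = ps.two_set_partition_test(
            truth.class_members(CLASS_PROPROLIF),
            truth.class_members(CLASS_PRODIFF),
            kept, sites, n_iter=n_iter, seed=it_seed)
        if (r.p_values[WINDOW_BINS] < 0.05).all():
            hits_two_set += 1
        prodiff = truth.class_members(CLASS_PRODIFF)
        kept_diff = [c for c in kept if c.gene_id in prodiff]
        ens = ps.randomized_apa_null(kept_diff, sites, n_iter=n_iter,
                                     seed=it_seed)
        if (ens.p_values[WINDOW_BINS] < 0.05).all():
            hits_apa_null += 1
    return {
        "n_cohorts": float(n_cohorts),
        "power_two_set": hits_two_set / n_cohorts,
        "power_apa_null": hits_apa_null / n_cohorts,
    }


def score_agreement_study(seed: int, n_perm: int = 10_000) -> dict:
    """score_window_compare vs closed-form pooled t and a label-permutation
    p-value, on generated score samples with known means."""
    from apamir.apa_assignment import ApaCall
    from apamir.io_formats import GenomicInterval, UTRModel

    rng = np.random.default_rng(seed)
    utr = UTRModel("g0", "g0", [GenomicInterval("c", 0, 3000, "+")],
                   "N" * 3000)
    call = ApaCall("g0", utr, [1500, 2999])

    def compare(mu5, mu3, n, do_perm=True):
        a = rng.normal(mu5, 0.1, n)
        b = rng.normal(mu3, 0.1, n)
        sites = [SeedSite("g0", 1200 + j, "f", True, pct=v)
                 for j, v in enumerate(a)]
        sites += [SeedSite("g0", 1500 + j, "f", True, pct=v)
                  for j, v in enumerate(b)]
        res = ps.score_window_compare([call], sites, kind="pct")
        sp2 = (((n - 1) * a.var(ddof=1) + (n - 1) * b.var(ddof=1))
               / (2 * n - 2))
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * 2 / n)
        p = 2 * stats.t.sf(abs(t), 2 * n - 2)
        if not do_perm:
            return res, t, p, None
        # label-permutation reference for the two-sided t
        obs = abs(t)
        pool = np.concatenate([a, b])
        perm_hits = 0
        for _ in range(n_perm):
            rng.shuffle(pool)
            pa, pb = pool[:n], pool[n:]
            sp2p = (((n - 1) * pa.var(ddof=1) + (n - 1) * pb.var(ddof=1))
                    / (2 * n - 2))
            tp = (pa.mean() - pb.mean()) / np.sqrt(sp2p * 2 / n)
            if abs(tp) >= obs:
                perm_hits += 1
        p_perm = (1 + perm_hits) / (1 + n_perm)
        return res, t, p, p_perm

    strong, t_s, p_s, _ = compare(0.6, 0.4, 200, do_perm=False)
    mod, t_m, p_m, p_perm = compare(0.515, 0.5, 150)
    return {
        "strong_t": strong.t_statistic,
        "strong_p": strong.p_value,
        "strong_t_closed_form_error": abs(strong.t_statistic - t_s),
        "strong_p_closed_form_error": abs(strong.p_value - p_s),
        "moderate_p": mod.p_value,
        "moderate_t_closed_form_error": abs(mod.t_statistic - t_m),
        "moderate_p_permutation": p_perm,
        "moderate_p_vs_permutation_error": abs(mod.p_value - p_perm),
    }


def expansion_study(seed: int, n_genes: int = 400) -> dict:
    """Codon-usage class recovery by competing gene-set expansion."""
    bundle = simulate(SimConfig(n_genes=n_genes, seed=int(seed)))
    vecs = [genesets.codon_usage(s, g) for g, s in bundle.cds.items()]
    sets = [genesets.GeneSet(name, members)
            for name, members in sorted(bundle.gene_sets.items())]
    out = {s.name: s for s in genesets.expand_competing(sets, vecs, 0.75)}
    diff = bundle.truth.class_members(CLASS_PRODIFF)
    prolif = bundle.truth.class_members(CLASS_PROPROLIF)
    correct = (len(out["pattern_like"].gene_ids & diff)
               + len(out["mphase_like"].gene_ids & prolif))
    wrong = (len(out["pattern_like"].gene_ids - diff)
             + len(out["mphase_like"].gene_ids - prolif))
    n_class = len(diff | prolif)
    return {
        "n_class_genes": float(n_class),
        "expansion_accuracy": correct / n_class if n_class else float("nan"),
        "expansion_false_positives": float(wrong),
        "expanded_size_prodiff": float(len(out["pattern_like"].gene_ids)),
        "expanded_size_proprolif": float(len(out["mphase_like"].gene_ids)),
    }
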