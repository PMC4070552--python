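"""End-to-end orchestration: simulate or load, then run every stage.

Stage order is fixed: parse -> fold -> trim -> consensus -> coverage and
windows -> GC fits -> errors and motifs -> heteroplasmy -> concordance ->
(optional) k-mer spectrum. The report is a plain JSON-serializable dict in
which every statistic carries its n and df.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .concordance import concordance_windows, pairwise_profile_correlation
from .coverage_profile import (
    CoverageProfile,
    fold_circular_overlap,
    scale_to_reference_mean,
    trim_retained_region,
    window_profile,
)
from .error_profile import (
    call_heteroplasmy,
    consensus_from_counts,
    error_coverage_correlation,
    motif_proximity_analysis,
    scan_iupac_motifs,
    site_error_rates,
    substitution_spectrum,
)
from .gc_bias import at_gc_coverage_ttest, compare_models_aic, fit_gc_regression, site_ancova, site_gc50
from .io_formats import SiteProfile, parse_pileup, read_bed_annotation, read_reference
from .kmer_spectrum import count_kmers, depth_from_peak, estimate_spectrum
from .synthetic_data import (
    SimulationConfig,
    emit_truth_and_pileups,
    generate_reference,
    simulate_reads,
    simulate_site_profiles,
    write_fastq,
)

logger = logging.getLogger("mitocovbias")

DEFAULTS = {
    "overlap": 0,
    "window": 50,
    "step": None,  # None -> non-overlapping (= window)
    "motif": "CCNGCC",
    "flank": 100,
    "high_freq": 0.01,
    "low_freq": 0.001,
    "min_depth": 100,
    "concordance_window": 250,
    "kmer_k": 25,
    "kmer_cutoff": None,
    "run_kmer": False,
    "kmer_read_depth": 50.0,
    "kmer_read_len": 100,
}


def _fit_to_dict(fit) -> dict:
    d = {
        "degree": fit.degree,
        "coefficients": [float(c) for c in fit.coefficients],
        "F": fit.F,
        "R2": fit.R2,
        "df": fit.df,
        "p": fit.p,
        "aic": fit.aic,
        "n": fit.n,
    }
    if fit.degree == 2:
        d["vertex_gc"] = fit.vertex_gc
    return d


def run_all(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run the whole pipeline from a flat config dict; returns the report.

    The config either sets ``simulate: true`` (with optional simulation
    overrides) or names input files: ``pileups`` (list), ``reference``
    (FASTA) and optionally ``annotation`` (BED). Missing inputs fail before
    any stage runs.
    """
    cfg = {**DEFAULTS, **config}
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # --- inputs -----------------------------------------------------------
    if cfg.get("simulate"):
        sim_keys = {f.name for f in SimulationConfig.__dataclass_fields__.values()}
        sim_cfg = SimulationConfig(
            **{k: v for k, v in cfg.items() if k in sim_keys}
        )
        reference, motifs = generate_reference(sim_cfg)
        profiles, truth = simulate_site_profiles(reference, sim_cfg, motifs)
        if out:
            emit_truth_and_pileups(profiles, truth, reference, out / "sim")
        features = reference.features
    else:
        missing = [k for k in ("pileups", "reference") if not cfg.get(k)]
        if missing:
            raise ValueError(
                f"config must set simulate=true or provide inputs: missing {missing}"
            )
        reference = read_reference(cfg["reference"])
        profiles = [
            parse_pileup(p, individual_id=Path(p).stem, ref_length=len(reference))
            for p in cfg["pileups"]
        ]
        features = (
            read_bed_annotation(cfg["annotation"], len(reference))
            if cfg.get("annotation")
            else []
        )
        reference.features = features
        truth = None

    L_ref = len(reference)
    report: dict = {
        "version": __version__,
        "seed": cfg.get("seed"),
        "config": {k: v for k, v in cfg.items() if isinstance(v, (int, float, str, bool, type(None)))},
        "n_individuals": len(profiles),
        "L_ref": L_ref,
    }

    # --- fold + trim ------------------------------------------------------
    overlap = int(cfg["overlap"])
    first_kept = int(cfg.get("keep_first", 1))
    last_kept = int(cfg.get("keep_last", L_ref))
    folded_depths = {}
    for p in profiles:
        depth = p.depth.astype(float)
        if overlap:
            depth = fold_circular_overlap(depth, L_ref, overlap)
        folded_depths[p.individual_id] = depth
    trimmed_profiles: list[SiteProfile] = []
    for p in profiles:
        counts = p.counts
        n_del = p.n_del
        if overlap:  # fold the count matrix the same way as the depth
            counts = counts[:L_ref].copy()
            counts[:overlap] += p.counts[L_ref:]
            n_del = n_del[:L_ref].copy()
            n_del[:overlap] += p.n_del[L_ref:]
        sl = slice(first_kept - 1, last_kept)
        trimmed_profiles.append(
            SiteProfile(
                p.individual_id,
                np.arange(last_kept - first_kept + 1),
                p.ref_bases[:L_ref][sl],
                counts[sl],
                n_del[sl],
            )
        )
    n_trimmed = L_ref - (last_kept - first_kept + 1)
    report["retained_region"] = {
        "first_kept": first_kept,
        "last_kept": last_kept,
        "n_retained": last_kept - first_kept + 1,
        "n_trimmed": n_trimmed,
    }

    # --- consensus --------------------------------------------------------
    region_ref = reference.sequence[first_kept - 1 : last_kept]
    consensus = consensus_from_counts(trimmed_profiles, np.array(list(region_ref)))

    # --- coverage profiles and scaling ------------------------------------
    span = (first_kept, last_kept)
    cov_profiles = [
        CoverageProfile(p.individual_id, p.depth.astype(float), span)
        for p in trimmed_profiles
    ]
    main_id = cfg.get("main_individual", cov_profiles[0].individual_id)
    scaled = scale_to_reference_mean(cov_profiles, main_id)
    main = next(p for p in cov_profiles if p.individual_id == main_id)
    report["coverage"] = {
        "main_individual": main_id,
        "mean": main.mean,
        "min": float(main.values.min()),
        "max": float(main.values.max()),
        "fold_range": float(main.values.max() / max(main.values.min(), 1.0)),
        "n_sites": len(main),
    }

    # --- windows + GC fits -------------------------------------------------
    window = int(cfg["window"])
    step = cfg["step"] or window
    table = window_profile(consensus, main.values, window, int(step))
    fit1 = fit_gc_regression(table, 1)
    fit2 = fit_gc_regression(table, 2)
    ttest = at_gc_coverage_ttest(main.values, consensus)
    report["gc_bias"] = {
        "n_windows": len(table),
        "linear": _fit_to_dict(fit1),
        "quadratic": _fit_to_dict(fit2),
        "delta_aic": compare_models_aic(fit1, fit2),
        "at_gc_ttest": dict(
            zip(("t", "df", "p", "mean_AT", "mean_GC"), ttest)
        ),
    }
    if features:
        gt = reference.gene_type_per_site()[first_kept - 1 : last_kept]
        if len(set(gt)) >= 2 and len(set(consensus) - {"N"}) >= 2:
            anc = site_ancova(main.values, np.array(list(consensus)), gt, site_gc50(consensus, window))
            report["ancova"] = {
                "n": anc["n"],
                "F": {term: float(f) for term, f in anc["anova"]["F"].dropna().items()},
                "reference_levels": anc["reference_levels"],
            }

    # --- errors and motifs --------------------------------------------------
    main_profile = next(p for p in trimmed_profiles if p.individual_id == main_id)
    rates = site_error_rates(main_profile, consensus)
    summary = rates.summary()
    spectrum_table, titv = substitution_spectrum(trimmed_profiles, consensus)
    hits = scan_iupac_motifs(consensus, cfg["motif"], circular=False)
    report["errors"] = {
        "site_error_rate": summary,
        "titv": titv,
        "substitution_rates": {
            x: {y: (None if np.isnan(v) else float(v)) for y, v in row.items()}
            for x, row in spectrum_table.iterrows()
        },
        "n_motif_hits": len(hits),
    }
    if hits:
        _, r, df, p = motif_proximity_analysis(main.values, hits, flank=int(cfg["flank"]))
        report["errors"]["motif_proximity"] = {"r": r, "df": df, "p": p}
    ecorr = error_coverage_correlation(rates.rates, main.values)
    report["errors"]["error_coverage_correlation"] = dict(zip(("r", "df", "p"), ecorr))

    # --- heteroplasmy -------------------------------------------------------
    calls, shared = call_heteroplasmy(
        trimmed_profiles,
        consensus,
        high_freq=float(cfg["high_freq"]),
        low_freq=float(cfg["low_freq"]),
        min_depth=int(cfg["min_depth"]),
    )
    report["heteroplasmy"] = {
        "n_calls": len(calls),
        "calls": [
            {
                "pos": c.pos,
                "carrier": c.carrier_individual,
                "alt_base": c.alt_base,
                "alt_freq": c.alt_freq,
                "max_other_freq": c.max_other_freq,
            }
            for c in calls
        ],
        "n_shared_variants": len(shared),
    }

    # --- concordance --------------------------------------------------------
    if len(scaled) >= 2:
        pairs = pairwise_profile_correlation(scaled)
        off = pairs[pairs["individual_a"] != pairs["individual_b"]]
        cw = concordance_windows(scaled, int(cfg["concordance_window"]))
        report["concordance"] = {
            "n_pairs": len(off),
            "r_min": float(off["r"].min()),
            "r_max": float(off["r"].max()),
            "r_mean": float(off["r"].mean()),
            "df": int(off["df"].iloc[0]),
            "most_concordant_window": int(cw["window_start"].iloc[0]),
            "least_concordant_window": int(cw["window_start"].iloc[-1]),
        }

    # --- k-mers (optional) --------------------------------------------------
    if cfg.get("run_kmer"):
        k = int(cfg["kmer_k"])
        if cfg.get("reads"):
            reads_src = cfg["reads"]
        else:
            reads = simulate_reads(
                reference,
                depth=float(cfg["kmer_read_depth"]),
                read_len=int(cfg["kmer_read_len"]),
                e0=float(cfg.get("e0", 0.001)),
                seed=int(cfg.get("seed", 0)) + 1,
            )
            reads_src = [seq for _, seq, _ in reads]
            if out:
                write_fastq(reads, out / "reads.fq")
        spectrum = count_kmers(reads_src, k=k, canonical=True)
        est = estimate_spectrum(spectrum, cfg.get("kmer_cutoff"))
        report["kmer"] = {
            "k": k,
            "error_threshold": est.error_threshold,
            "peak_multiplicity": est.peak_multiplicity,
            "total_kmer_instances": est.total_kmer_instances,
            "error_fraction": est.error_fraction,
            "per_base_error": est.per_base_error,
            "depth_estimate": depth_from_peak(
                est.peak_multiplicity, float(cfg["kmer_read_len"]), k
            ),
        }

    if truth is not None:
        truth_set = {
            (h["pos"] - (first_kept - 1), h["individual_id"], h["alt_base"])
            for h in truth.heteroplasmies
            if first_kept - 1 <= h["pos"] < last_kept
        }
        called_set = {(c.pos, c.carrier_individual, c.alt_base) for c in calls}
        tp = len(truth_set & called_set)
        report["heteroplasmy"]["recovery"] = {
            "n_true": len(truth_set),
            "precision": tp / len(called_set) if called_set else float("nan"),
            "recall": tp / len(truth_set) if truth_set else float("nan"),
        }

    if out:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
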