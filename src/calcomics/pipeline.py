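"""End-to-end orchestration: simulate (or load) a cohort, compute every layer's
scores, contrast the calcification groups, and write tidy result tables plus a
run manifest.

The stage order mirrors the study workflow: genome-instability scars ->
immune scoring -> metabolome -> group comparisons -> survival. Each stage logs
to stderr, failures abort with a stage-named error, and partial outputs are
retained on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .expression import score_signatures, infer_tme, cluster_mrna_subtype
from .metabolome import da_score, da_table, lipid_subclass_fc, prefilter_features
from .mutations import compute_tmb
from .scars import hrd_table
from .simulate import CohortSpec, generate_cohort
from .stats import attach_fdr, compare_continuous, cox_hazard, feature_frequency_table

log = logging.getLogger("calcomics")

DEFAULT_CONTRASTS = (
    ("high_suspicion", "probably_benign"),
    ("high_suspicion", "negative"),
)


def _stage(name):
    def wrap(fn):
        def run(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out

        return run

    return wrap


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the full pipeline from a config mapping (or YAML path).

    Recognized config keys: ``simulate`` (a :class:`CohortSpec` field mapping;
    required in this release — loading pre-made layers goes through the io
    module and the individual stage functions), ``contrasts`` (list of
    [positive, reference] group pairs), ``cox_covariates``, ``seed``.
    Returns the manifest dict; all outputs are TSV/JSON files under
    ``outdir``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    seed = int(config.get("seed", 0))
    contrasts = [tuple(c) for c in config.get("contrasts", DEFAULT_CONTRASTS)]
    covariates = tuple(config.get("cox_covariates", ("age", "tumor_size_cat", "node_status")))
    sim_cfg = dict(config.get("simulate", {}))
    sim_cfg.setdefault("seed", seed)
    spec = CohortSpec(**sim_cfg)

    cohort_obj = _stage("simulate")(generate_cohort)(spec)
    cohort_obj.write(out / "inputs")
    cohort = cohort_obj.cohort.set_index("sample")
    groups = cohort["group"]

    # --- genome instability ------------------------------------------------
    @_stage("scars")
    def scars_stage():
        scars = hrd_table(cohort_obj.segments, cohort_obj.build)
        tmb = compute_tmb(cohort_obj.mutations).rename_axis("sample").reset_index()
        scars = scars.merge(tmb, on="sample", how="left").fillna({"tmb": 0.0})
        scars.to_csv(out / "scars.tsv", sep="\t", index=False)
        return scars

    scars = scars_stage()

    # --- immune scoring ----------------------------------------------------
    @_stage("immune")
    def immune_stage():
        sig = score_signatures(cohort_obj.expression, cohort_obj.signatures)
        tme = infer_tme(cohort_obj.expression, cohort_obj.tme_reference)
        sig.rename_axis("signature").to_csv(out / "immune_scores.tsv", sep="\t")
        tme.rename_axis("cell_type").to_csv(out / "tme_scores.tsv", sep="\t")
        cluster_mrna_subtype(cohort_obj.expression, k=4, seed=seed)
        return sig, tme

    sig_scores, _tme = immune_stage()

    # --- metabolome --------------------------------------------------------
    @_stage("metabolome")
    def metab_stage():
        prefilter_features(cohort_obj.metabolites, cohort_obj.metabolites_normal, top_sd=200)
        results = []
        for positive, reference in contrasts:
            res = da_score(
                cohort_obj.metabolites,
                groups,
                cohort_obj.metabolite_annotation,
                positive_group=positive,
                reference_group=reference,
            )
            tab = da_table(res)
            tab.insert(0, "contrast", f"{positive}_vs_{reference}")
            results.append(tab)
        da = pd.concat(results, ignore_index=True)
        da.to_csv(out / "da_scores.tsv", sep="\t", index=False)
        fc = lipid_subclass_fc(
            cohort_obj.lipids, groups, cohort_obj.lipid_annotation, *contrasts[0]
        )
        fc.to_csv(out / "lipid_subclass_fc.tsv", sep="\t", index=False)
        return da

    metab_stage()

    # --- comparisons -------------------------------------------------------
    @_stage("comparisons")
    def compare_stage():
        muts = cohort_obj.mutations
        events = (
            muts[muts["is_nonsynonymous"]]
            .assign(v=1)
            .pivot_table(index="Hugo_Symbol", columns="Tumor_Sample_Barcode", values="v", aggfunc="max")
            .reindex(columns=cohort.index)
            .fillna(0)
            .astype(int)
        )
        freq_tabs = []
        for positive, reference in contrasts:
            tab = feature_frequency_table(events, groups, positive, reference)
            tab.insert(0, "contrast", f"{positive}_vs_{reference}")
            freq_tabs.append(tab)
        freq = pd.concat(freq_tabs, ignore_index=True)
        freq.to_csv(out / "frequencies.tsv", sep="\t", index=False)

        sig_results = []
        for positive, reference in contrasts:
            fam = [
                compare_continuous(sig_scores.loc[s].rename(s), groups, positive, reference)
                for s in sig_scores.index
            ]
            for r in attach_fdr(fam):
                sig_results.append({"contrast": r.contrast, **{k: v for k, v in r.__dict__.items() if k != "contrast"}})
        pd.DataFrame(sig_results).to_csv(out / "signature_contrasts.tsv", sep="\t", index=False)
        return freq

    compare_stage()

    # --- survival ----------------------------------------------------------
    @_stage("survival")
    def survival_stage():
        rows = []
        for endpoint in ("os", "dmfs", "rfs"):
            for positive, reference in contrasts:
                try:
                    res = cox_hazard(cohort.reset_index(), endpoint, positive, reference, covariates=covariates)
                    rows.append(res.__dict__)
                except ValueError as exc:
                    log.warning("survival %s %s vs %s skipped: %s", endpoint, positive, reference, exc)
        surv = pd.DataFrame(rows)
        surv.to_csv(out / "survival.tsv", sep="\t", index=False)
        return surv

    survival_stage()

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "contrasts": [list(c) for c in contrasts],
        "cox_covariates": list(covariates),
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_samples": int(len(cohort)),
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.removeHandler(handler)
    handler.close()
    return manifest
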