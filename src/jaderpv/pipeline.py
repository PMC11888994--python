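"""One-command orchestration of the full analysis.

Stage order follows the analysis flowchart: join the four tables, keep cases
where the target drug is a suspect, extract the SMQ cohort, classify
indications and outcomes, run the time-to-onset analysis (quartiles, Weibull,
hazard typing), Kaplan-Meier with pairwise log-rank, association-rule mining,
and the summary tables.  A JSON manifest records the case count entering and
leaving every stage — the exclusion counts a report usually states only
implicitly — and all stage tables are written as CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml

from . import case_extraction as ce
from . import rule_mining as rm
from . import sr_tables as srt
from . import survival_compare as sc
from . import time_to_onset as tto
from .errors import ConfigurationError, PipelineStageError
from .records import IndicationCategory
from .synthetic_data import TARGET_DRUG, SynthConfig, generate_dataset

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either the four table paths or a synthetic-data configuration must be
    present (not neither).  All randomness flows from ``seed`` (it overrides
    the synthetic config's own seed so one number reproduces the run).
    """

    demo_path: Optional[str] = None
    drug_path: Optional[str] = None
    hist_path: Optional[str] = None
    reac_path: Optional[str] = None
    synth: Optional[SynthConfig] = None
    drug_name: str = TARGET_DRUG
    smq_path: Optional[str] = None
    keyword_rules_path: Optional[str] = None
    binning: rm.TimeBinning = field(default_factory=rm.TimeBinning)
    mining: rm.MiningConfig = field(default_factory=rm.MiningConfig)
    quantile_method: str = "linear"
    bonferroni: bool = False
    indication_totals: Optional[Mapping[str, int]] = None
    out_dir: Optional[str] = None
    seed: Optional[int] = None
    encoding: Optional[str] = None

    def __post_init__(self) -> None:
        have_paths = all((self.demo_path, self.drug_path, self.hist_path, self.reac_path))
        if not have_paths and self.synth is None:
            raise ConfigurationError("provide the four table paths or a synthetic config")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        synth = doc.pop("synth", None)
        mining = doc.pop("mining", None)
        kwargs = dict(doc)
        if synth is not None:
            kwargs["synth"] = SynthConfig(**synth)
        if mining is not None:
            kwargs["mining"] = rm.MiningConfig(**mining)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    manifest: dict
    tables: dict[str, pd.DataFrame]
    out_dir: Optional[Path] = None


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and return the manifest plus every stage table.

    Stage case counts in the manifest are monotonically non-increasing along
    the filter chain.  An input yielding zero cohort cases completes with
    empty downstream tables and a logged warning rather than failing.
    """
    manifest: dict = {"drug_name": config.drug_name, "stages": {}}
    stages = manifest["stages"]

    @_stage("load")
    def load():
        if config.synth is not None:
            synth = config.synth
            if config.seed is not None:
                synth = dataclasses.replace(synth, rng_seed=config.seed)
            ds = generate_dataset(synth)
            records = {
                k: srt.records_from_frame(getattr(ds, k), k)
                for k in ("demo", "drug", "hist", "reac")
            }
            manifest["synthetic"] = True
            manifest["truth"] = ds.truth
            return records
        manifest["synthetic"] = False
        return {
            "demo": srt.read_table(config.demo_path, "demo", encoding=config.encoding),
            "drug": srt.read_table(config.drug_path, "drug", encoding=config.encoding),
            "hist": srt.read_table(config.hist_path, "hist", encoding=config.encoding),
            "reac": srt.read_table(config.reac_path, "reac", encoding=config.encoding),
        }

    records = load()
    for kind in ("demo", "drug", "hist", "reac"):
        stages[f"rows_{kind}"] = len(records[kind])

    @_stage("join")
    def join():
        cases, stats = srt.join_cases(
            records["demo"], records["drug"], records["hist"], records["reac"], with_stats=True
        )
        stages["joined_cases"] = stats["n_cases"]
        stages["orphan_rows"] = stats["orphans"]
        return cases

    cases = join()

    @_stage("suspect_filter")
    def suspect():
        kept = srt.filter_suspect(cases, config.drug_name)
        stages["suspect_cases"] = len(kept)
        return kept

    cases = suspect()

    @_stage("smq_extraction")
    def smq_extract():
        smq = ce.load_gi_perforation_smq(config.smq_path)
        kept = ce.extract_smq_cases(cases, smq)
        stages["smq_cases"] = len(kept)
        if not kept:
            logger.warning("no cases matched the SMQ; downstream tables will be empty")
        return smq, kept

    smq, cases = smq_extract()

    @_stage("classification")
    def classify():
        rules = (
            ce.KeywordRuleSet.from_yaml(config.keyword_rules_path)
            if config.keyword_rules_path
            else ce.load_default_keyword_rules()
        )
        out = ce.assign_indications(cases, config.drug_name, rules)
        out = ce.annotate_outcomes(out)
        return out

    cases = classify()

    tables: dict[str, pd.DataFrame] = {}

    @_stage("descriptives")
    def descriptives():
        tables["demographics"] = ce.demographic_table(cases)
        totals = None
        if config.indication_totals:
            totals = {IndicationCategory(k): v for k, v in config.indication_totals.items()}
        tables["indications"] = ce.indication_counts(cases, totals)
        tables["outcomes"] = ce.outcome_mosaic_table(cases)

    descriptives()

    @_stage("time_to_onset")
    def onset():
        annotated = tto.annotate_onset(cases, config.drug_name, smq)
        samples = tto.collect_onset_samples(annotated)
        stages["tto_cases"] = samples["all"].n if "all" in samples else 0
        tables["tto_summary"] = tto.tto_summary_table(
            samples, quantile_method=config.quantile_method
        )
        return annotated, samples

    cases, samples = onset()

    @_stage("survival")
    def survival():
        curves = [
            sc.km_to_frame(sc.km_estimate(s)) for s in samples.values() if s.n >= 1
        ]
        tables["km_curves"] = (
            pd.concat(curves, ignore_index=True)
            if curves
            else pd.DataFrame(columns=["stratum", "time", "at_risk", "events", "survival"])
        )
        tables["logrank"] = sc.pairwise_logrank(samples, bonferroni=config.bonferroni, min_n=2)

    survival()

    @_stage("rule_mining")
    def mining():
        transactions, stats = rm.build_transactions(cases, config.binning, with_stats=True)
        stages["transactions"] = stats["n_transactions"]
        stages["transactions_dropped"] = stats["dropped"]
        if transactions:
            miner = rm.AssociationRuleMiner(**_mining_kwargs(config.mining)).fit(transactions)
            tables["rules"] = miner.rules_frame()
        else:
            tables["rules"] = rm.rules_to_frame([])

    mining()

    @_stage("cases_table")
    def cases_table():
        rows = []
        for c in cases:
            rows.append(
                {
                    "case_id": c.case_id,
                    "sex": c.sex.value,
                    "age_band": c.age_band.value,
                    "indications": ";".join(sorted(i.value for i in c.indications)),
                    "n_suspect_drugs": len(c.suspect_drugs),
                    "onset_days": "" if c.onset_days is None else c.onset_days,
                    "outcome_class": c.outcome_class.value if c.outcome_class else "",
                }
            )
        tables["cases"] = pd.DataFrame(
            rows,
            columns=[
                "case_id",
                "sex",
                "age_band",
                "indications",
                "n_suspect_drugs",
                "onset_days",
                "outcome_class",
            ],
        )

    cases_table()

    out_dir = None
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, frame in tables.items():
            frame.to_csv(out_dir / f"{name}.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(manifest=manifest, tables=tables, out_dir=out_dir)


def _mining_kwargs(cfg: rm.MiningConfig) -> dict:
    return {
        "min_support": cfg.min_support,
        "min_confidence": cfg.min_confidence,
        "maxlen": cfg.maxlen,
        "max_lhs": cfg.max_lhs,
        "chi2_threshold": cfg.chi2_threshold,
        "lift_min": cfg.lift_min,
        "chi2_d": cfg.chi2_d,
    }
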