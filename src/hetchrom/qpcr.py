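"""ChIP-qPCR enrichment by the delta-Ct (percent-of-input) method.

A quantitative-PCR cycle threshold (Ct) drops by one cycle per doubling of
template.  Enrichment of immunoprecipitated (IP) DNA relative to input
chromatin is therefore

    percent_input = 100 * 2^(Ct_input_adj - Ct_IP)

where the input Ct is first adjusted for the fraction of chromatin used as
input: Ct_input_adj = Ct_input - log2(1 / input_fraction).  Amplification
efficiency is taken as exactly 2 per cycle (no standard-curve correction).
Technical replicates are averaged on the Ct scale; biological replicates
are summarized (mean, SD with n-1 denominator, n) after the exponential
transform.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .errors import ParameterError


@dataclasses.dataclass(frozen=True)
class QpcrMeasurement:
    sample: str
    target: str
    Ct: float
    is_input: bool
    input_fraction: float | None = None  # fraction of chromatin used as input
    replicate: str = "1"

    def __post_init__(self) -> None:
        if not 0 < self.Ct < 45:
            raise ParameterError(f"Ct {self.Ct} outside (0, 45)")
        if self.is_input and not (
            self.input_fraction is not None and 0 < self.input_fraction <= 1
        ):
            raise ParameterError("input wells need input_fraction in (0, 1]")


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    sample: str
    target: str
    mean: float  # percent of input
    sd: float  # nan for a single replicate
    n: int


def percent_input(ct_input: float, input_fraction: float, ct_ip: float) -> float:
    """Percent-of-input enrichment for one IP/input Ct pair."""
    if input_fraction <= 0:
        raise ParameterError(f"input_fraction must be > 0, got {input_fraction}")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


def fold_enrichment(a: EnrichmentResult, b: EnrichmentResult) -> tuple[float, float]:
    """Ratio of mean enrichments a/b with first-order SD propagation.

    sd_ratio = ratio * sqrt((sd_a / mean_a)^2 + (sd_b / mean_b)^2)
    """
    if b.mean == 0:
        raise ParameterError("zero denominator enrichment")
    ratio = a.mean / b.mean
    terms = 0.0
    if a.mean != 0 and not math.isnan(a.sd):
        terms += (a.sd / a.mean) ** 2
    if not math.isnan(b.sd):
        terms += (b.sd / b.mean) ** 2
    return ratio, abs(ratio) * math.sqrt(terms)


def replicate_summary(values, group_keys=None) -> pd.DataFrame:
    """Mean, sample SD (n-1) and n per group; SD is NaN for n = 1."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float)})
    if group_keys is None:
        df["group"] = "all"
        group_keys_cols = ["group"]
    else:
        keys = pd.DataFrame(group_keys)
        df = pd.concat([keys.reset_index(drop=True), df], axis=1)
        group_keys_cols = list(keys.columns)
    out = (
        df.groupby(group_keys_cols, sort=False)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    return out


def enrich(table: pd.DataFrame) -> list[EnrichmentResult]:
    """Percent-of-input enrichment per (sample, target) from a Ct table.

    ``table`` columns: sample, target, replicate, Ct, is_input,
    input_fraction.  Within each (sample, target, replicate), technical
    wells are averaged on the Ct scale; one percent-input value per
    biological replicate is then summarized across replicates.
    """
    required = {"sample", "target", "replicate", "Ct", "is_input", "input_fraction"}
    missing = required - set(table.columns)
    if missing:
        raise ParameterError(f"Ct table missing columns {sorted(missing)}")
    results = []
    for (sample, target), grp in table.groupby(["sample", "target"], sort=False):
        values = []
        for _, rep in grp.groupby("replicate", sort=False):
            inputs = rep[rep["is_input"].astype(bool)]
            ips = rep[~rep["is_input"].astype(bool)]
            if inputs.empty or ips.empty:
                raise ParameterError(
                    f"{sample}/{target}: replicate lacks input or IP wells"
                )
            frac = float(inputs["input_fraction"].iloc[0])
            values.append(
                percent_input(
                    float(inputs["Ct"].mean()), frac, float(ips["Ct"].mean())
                )
            )
        arr = np.array(values)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else math.nan
        results.append(
            EnrichmentResult(
                sample=str(sample),
                target=str(target),
                mean=float(arr.mean()),
                sd=sd,
                n=len(arr),
            )
        )
    return results


def enrichment_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": r.sample,
                "target": r.target,
                "percent_input_mean": r.mean,
                "percent_input_sd": r.sd,
                "n": r.n,
            }
            for r in results
        ]
    )
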