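"""Tabular readers/writers for expression profiles and exchange maps."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .gpr import ExpressionProfile

__all__ = [
    "read_expression",
    "write_expression",
    "read_exchange_map",
    "write_exchange_map",
]


def read_expression(path: str | Path, condition: str = "") -> ExpressionProfile:
    """Read a per-gene TSV: columns gene, value, optional p_value / log_fc.

    Duplicate gene rows (multiple probes) are collapsed to their maximum
    value; p_value and log_fc then keep the row with the maximal value.
    """
    df = pd.read_csv(path, sep="\t")
    if missing := {"gene", "value"} - set(df.columns):
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    df = df.sort_values("value").drop_duplicates("gene", keep="last")
    p_value = (
        dict(zip(df.gene, df.p_value.astype(float))) if "p_value" in df.columns else None
    )
    log_fc = dict(zip(df.gene, df.log_fc.astype(float))) if "log_fc" in df.columns else None
    return ExpressionProfile.from_records(
        dict(zip(df.gene, df.value.astype(float))),
        p_value=p_value,
        log_fc=log_fc,
        condition=condition,
    )


def write_expression(profile: ExpressionProfile, path: str | Path) -> None:
    rows = []
    for gene in sorted(profile.values):
        row = {"gene": gene, "value": profile.values[gene]}
        if profile.p_value:
            row["p_value"] = profile.p_value.get(gene, float("nan"))
        if profile.log_fc:
            row["log_fc"] = profile.log_fc.get(gene, float("nan"))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_exchange_map(path: str | Path) -> dict[str, list[str]]:
    """TSV with columns metabolite, reaction: one exchange reaction per row."""
    df = pd.read_csv(path, sep="\t")
    if missing := {"metabolite", "reaction"} - set(df.columns):
        raise ValueError(f"exchange map missing columns: {sorted(missing)}")
    out: dict[str, list[str]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.metabolite), []).append(str(r.reaction))
    return out


def write_exchange_map(mapping: dict[str, list[str]], path: str | Path) -> None:
    rows = [
        {"metabolite": met, "reaction": rid}
        for met in sorted(mapping)
        for rid in mapping[met]
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
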