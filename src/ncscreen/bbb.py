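"""Rule-based blood–brain-barrier permeability scoring.

A compound passes the CNS permeability screen to the degree it satisfies five
physicochemical criteria, each worth 20% of the score:

1. molecular weight ≤ 400 Da
2. −0.5 ≤ LogP ≤ 5
3. hydrogen-bond donors ≤ 3
4. hydrogen-bond acceptors ≤ 7
5. TPSA ≤ 90 Å²

All bounds are inclusive. Descriptors come from the shared descriptor layer
(:mod:`ncscreen.chem`), so the score is consistent with SAR profiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .chem import CompoundRecord, DescriptorSet, compute_descriptors

MW_MAX = 400.0
LOGP_MIN, LOGP_MAX = -0.5, 5.0
HBD_MAX = 3
HBA_MAX = 7
TPSA_MAX = 90.0

_CRITERIA = ("mw_ok", "logp_ok", "hbd_ok", "hba_ok", "tpsa_ok")


@dataclass(frozen=True)
class BBBResult:
    """Per-criterion pass flags and the aggregate permeability score."""

    compound_id: str
    mw_ok: bool
    logp_ok: bool
    hbd_ok: bool
    hba_ok: bool
    tpsa_ok: bool

    @property
    def n_passed(self) -> int:
        return sum(getattr(self, c) for c in _CRITERIA)

    @property
    def score_fraction(self) -> float:
        return self.n_passed / len(_CRITERIA)

    @property
    def score_percent(self) -> int:
        return 20 * self.n_passed


def bbb_score(descriptors: DescriptorSet, compound_id: str = "") -> BBBResult:
    """Evaluate the five permeability criteria on a descriptor set."""
    for field_name in ("mol_wt", "log_p", "h_donors", "h_acceptors", "tpsa"):
        value = getattr(descriptors, field_name, None)
        if value is None or not math.isfinite(float(value)):
            raise ValueError(f"descriptor {field_name!r} is missing or non-finite")
    return BBBResult(
        compound_id=compound_id,
        mw_ok=descriptors.mol_wt <= MW_MAX,
        logp_ok=LOGP_MIN <= descriptors.log_p <= LOGP_MAX,
        hbd_ok=descriptors.h_donors <= HBD_MAX,
        hba_ok=descriptors.h_acceptors <= HBA_MAX,
        tpsa_ok=descriptors.tpsa <= TPSA_MAX,
    )


def score_compound(record: CompoundRecord | str, compound_id: str = "") -> BBBResult:
    """Compute descriptors from a structure and score it."""
    if isinstance(record, CompoundRecord) and not compound_id:
        compound_id = record.id
    return bbb_score(compute_descriptors(record), compound_id=compound_id)


def score_table(records: list[CompoundRecord]) -> pd.DataFrame:
    """Score many compounds; one row per compound with descriptors, flags, score."""
    rows = []
    for r in records:
        d = compute_descriptors(r)
        res = bbb_score(d, compound_id=r.id)
        rows.append(
            {
                "id": r.id,
                "mw": d.mol_wt,
                "logp": d.log_p,
                "hbd": d.h_donors,
                "hba": d.h_acceptors,
                "tpsa": d.tpsa,
                "mw_ok": res.mw_ok,
                "logp_ok": res.logp_ok,
                "hbd_ok": res.hbd_ok,
                "hba_ok": res.hba_ok,
                "tpsa_ok": res.tpsa_ok,
                "score_percent": res.score_percent,
            }
        )
    return pd.DataFrame(rows)
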