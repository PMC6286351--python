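"""Curation of in-vitro turnover-number records.

In-vitro kcat values aggregated from kinetics databases (BRENDA, SABIO-RK,
MetaCyc) carry mutants, inhibited assays, cross-database duplicates of the
same experiment and entries that do not correspond to any reaction in the
metabolic model.  The curation cascade drops these in a fixed, logged order:

1. records flagged as mutant enzymes;
2. records flagged as measured in the presence of inhibitors;
3. cross-database duplicates from the same publication and reaction,
   keeping BRENDA over MetaCyc over SABIO-RK;
4. records whose key does not map to a network reaction;
5. among remaining same-reaction conflicts, a deterministic preference
   comparator keeps one record: in-vivo-like assay conditions first, then
   recency, then closeness to the group's median log value.

Every drop is recorded with the rule that fired, so curation of n records is
fully auditable and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TurnoverRecord", "CurationResult", "curate_kcat_records"]

_DB_PREFERENCE = {"BRENDA": 0, "METACYC": 1, "SABIO": 2}


@dataclass
class TurnoverRecord:
    """One turnover observation before or after curation."""

    record_id: str
    reaction_key: str  # raw key; resolved via reaction_map
    value: float  # s^-1
    source_db: str = "BRENDA"  # BRENDA | METACYC | SABIO
    publication_id: str = ""
    year: int = 2000
    mutant: bool = False
    inhibitor_note: bool = False
    assay_ph: float | None = None
    assay_temperature: float | None = None  # °C
    kind: str = "in_vitro_kcat"  # in_vitro_kcat | in_vivo_kappmax
    reaction_id: str | None = field(default=None)  # filled by curation

    def in_vivo_like(self) -> bool:
        """Assay conditions in a physiological window (pH 6-8, 25-42 °C)."""
        ph_ok = self.assay_ph is not None and 6.0 <= self.assay_ph <= 8.0
        t_ok = (
            self.assay_temperature is not None
            and 25.0 <= self.assay_temperature <= 42.0
        )
        return ph_ok and t_ok


@dataclass
class CurationResult:
    kept: list[TurnoverRecord]
    drop_log: pd.DataFrame  # columns: record_id, rule

    def to_tsv(self, kept_path, log_path) -> None:
        pd.DataFrame(
            [
                {
                    "record_id": r.record_id,
                    "reaction_id": r.reaction_id,
                    "value_per_s": r.value,
                    "source_db": r.source_db,
                    "publication_id": r.publication_id,
                }
                for r in self.kept
            ]
        ).to_csv(kept_path, sep="\t", index=False)
        self.drop_log.to_csv(log_path, sep="\t", index=False)


def curate_kcat_records(
    records: list[TurnoverRecord],
    reaction_map: dict[str, str],
) -> CurationResult:
    """Apply the curation cascade; returns kept records plus a drop log.

    ``reaction_map`` resolves raw record keys (EC number + substrate tags or
    database reaction ids) to network reaction ids; keys absent from the map
    are treated as unmappable and dropped.
    """
    drops: list[dict] = []
    pool = list(records)

    def drop(rec: TurnoverRecord, rule: str) -> None:
        drops.append({"record_id": rec.record_id, "rule": rule})

    # 1-2: mutants and inhibited assays
    stage = []
    for r in pool:
        if r.mutant:
            drop(r, "mutant")
        elif r.inhibitor_note:
            drop(r, "inhibitor")
        else:
            stage.append(r)
    pool = stage

    # 3: cross-database duplicates (same publication, same reaction key)
    groups: dict[tuple[str, str], list[TurnoverRecord]] = {}
    for r in pool:
        groups.setdefault((r.publication_id, r.reaction_key), []).append(r)
    stage = []
    for recs in groups.values():
        if len({r.source_db for r in recs}) > 1:
            recs_sorted = sorted(
                recs,
                key=lambda r: (_DB_PREFERENCE.get(r.source_db.upper(), 99), r.record_id),
            )
            stage.append(recs_sorted[0])
            for r in recs_sorted[1:]:
                drop(r, "cross_database_duplicate")
        else:
            stage.extend(recs)
    pool = stage

    # 4: mapping to network reactions
    stage = []
    for r in pool:
        rid = r.reaction_id or reaction_map.get(r.reaction_key)
        if rid is None:
            drop(r, "unmapped")
        else:
            r.reaction_id = rid
            stage.append(r)
    pool = stage

    # 5: same-reaction conflicts -> deterministic preference comparator
    by_rxn: dict[str, list[TurnoverRecord]] = {}
    for r in pool:
        by_rxn.setdefault(r.reaction_id, []).append(r)
    kept: list[TurnoverRecord] = []
    for recs in by_rxn.values():
        if len(recs) == 1:
            kept.append(recs[0])
            continue
        median_log = float(np.median([np.log10(r.value) for r in recs]))
        recs_sorted = sorted(
            recs,
            key=lambda r: (
                not r.in_vivo_like(),
                -r.year,
                abs(np.log10(r.value) - median_log),
                r.record_id,
            ),
        )
        kept.append(recs_sorted[0])
        for r in recs_sorted[1:]:
            drop(r, "conflict_preference")
    kept.sort(key=lambda r: r.record_id)
    log = pd.DataFrame(drops, columns=["record_id", "rule"])
    return CurationResult(kept, log)
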