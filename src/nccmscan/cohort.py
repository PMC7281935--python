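"""Cohort metadata: loading and descriptive summaries.

The packaged fixture ``data/glioma_cohort_39.tsv`` describes a 39-patient
glioblastoma cohort table (age, sex, subtype, tumor purity, coverage, and
per-sample concordant SPM/SIM counts); the single hyper-mutated recurrent
sample is flagged for exclusion from cohort mutation totals.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources
from statistics import median

import pandas as pd

SUBTYPES = {"CL", "MS", "PN", "n/a"}
REQUIRED_COLUMNS = [
    "sample_id", "grade", "age", "sex", "survival_days", "subtype",
    "purity", "depth", "spm_count", "sim_count", "recurrent",
]


class MetadataFormatError(ValueError):
    pass


@dataclass
class SampleMeta:
    sample_id: str
    grade: str
    age: int
    sex: str
    survival_days: int
    subtype: str
    purity: float
    depth: float
    spm_count: int
    sim_count: int
    recurrent: bool
    hypermutated: bool = False

    @property
    def total_mutations(self) -> int:
        return self.spm_count + self.sim_count


def packaged_metadata_path():
    """Path to the packaged cohort metadata fixture."""
    return resources.files("nccmscan").joinpath("data/glioma_cohort_39.tsv")


def load_metadata(path=None) -> list[SampleMeta]:
    """Parse a cohort metadata TSV into SampleMeta records.

    Raises MetadataFormatError naming the offending column or row.
    """
    if path is None:
        path = packaged_metadata_path()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)  # 'n/a' is a literal subtype
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataFormatError(f"missing required column(s): {', '.join(missing)}")
    metas = []
    for i, row in df.iterrows():
        try:
            meta = SampleMeta(
                sample_id=str(row["sample_id"]),
                grade=str(row["grade"]),
                age=int(row["age"]),
                sex=str(row["sex"]),
                survival_days=int(row["survival_days"]),
                subtype=str(row["subtype"]),
                purity=float(row["purity"]),
                depth=float(row["depth"]),
                spm_count=int(row["spm_count"]),
                sim_count=int(row["sim_count"]),
                recurrent=str(row["recurrent"]).strip() in ("1", "True", "true"),
                hypermutated=str(row.get("hypermutated", "0")).strip() in ("1", "True", "true"),
            )
        except (TypeError, ValueError) as exc:
            raise MetadataFormatError(f"row {i + 1} (sample {row.get('sample_id')}): {exc}") from exc
        if meta.age <= 0:
            raise MetadataFormatError(f"row {i + 1}: non-positive age {meta.age}")
        if meta.subtype not in SUBTYPES:
            raise MetadataFormatError(f"row {i + 1}: unknown subtype {meta.subtype!r}")
        if meta.spm_count < 0 or meta.sim_count < 0:
            raise MetadataFormatError(f"row {i + 1}: negative mutation count")
        metas.append(meta)
    return metas


def cohort_summary(metas: list[SampleMeta], exclude: list[str] | None = None) -> dict:
    """Descriptive summary of the cohort.

    Mutation totals are reported for all samples and with hyper-mutated
    samples excluded. ``exclude`` overrides the exclusion set; by default
    samples flagged ``hypermutated`` in the metadata are excluded, falling
    back to any sample whose SPM+SIM total exceeds 10x the cohort median.
    """
    if not metas:
        raise ValueError("empty cohort")
    ages = [m.age for m in metas]
    totals = [m.total_mutations for m in metas]
    if exclude is not None:
        excluded_ids = set(exclude)
    else:
        excluded_ids = {m.sample_id for m in metas if m.hypermutated}
        if not excluded_ids:
            cutoff = 10 * median(totals)
            excluded_ids = {m.sample_id for m in metas if m.total_mutations > cutoff}
    kept = [m for m in metas if m.sample_id not in excluded_ids]

    def counts(attr):
        out: dict[str, int] = {}
        for m in metas:
            out[getattr(m, attr)] = out.get(getattr(m, attr), 0) + 1
        return out

    return {
        "n": len(metas),
        "age_median": median(ages),
        "age_min": min(ages),
        "age_max": max(ages),
        "sex_counts": counts("sex"),
        "subtype_counts": counts("subtype"),
        "recurrent_count": sum(m.recurrent for m in metas),
        "per_sample_totals": {m.sample_id: m.total_mutations for m in metas},
        "spm_total": sum(m.spm_count for m in metas),
        "sim_total": sum(m.sim_count for m in metas),
        "excluded_hypermutated": sorted(excluded_ids),
        "spm_total_excl": sum(m.spm_count for m in kept),
        "sim_total_excl": sum(m.sim_count for m in kept),
        "n_excl": len(kept),
    }


def metadata_frame(metas: list[SampleMeta]) -> pd.DataFrame:
    return pd.DataFrame([asdict(m) for m in metas])
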