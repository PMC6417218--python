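"""Packaged reference tables: the 38 characterized candidate promoters and
the four synthetic RBS designs.

Both tables are verbatim transcriptions of published measurements for
*Zymomonas mobilis* ZM4 and ship with the package as plain TSV. The
candidate-promoter table carries, per gene, the per-platform average log2
expression (microarray, RNA-seq, proteomics), the measured EGFP/opmCherry
strength ratio in exponential (log) and stationary phase with replicate SDs,
and the assigned strength class (19 strong / 9 medium / 10 weak). One row
(the plasmid promoter Po1721) has no omics values. The RBS table holds four
synthetic ribosome binding sites with predicted translation initiation rates
10 / 1,000 / 10,000 / 15,000.

Integrity is enforced with a SHA-256 checksum plus schema invariants at load
time.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .errors import FixtureError
from .flow import RBSDesign

__all__ = ["load_table1_fixture", "load_table2_fixture"]

_CHECKSUMS = {
    "table1.tsv": "36928f25f3d69deff407021b631c73b3cea2f67e32539cd4dcdf8edb54d4c53c",
    "table2.tsv": "0df0deeb320c326132ae8cd0ad374e1254dc3980b020dad426a7e7dca9e269ea",
}

_EXPECTED_CLASS_COUNTS = {"strong": 19, "medium": 9, "weak": 10}

#: Map from fixture column to the platform names used elsewhere.
PLATFORM_COLUMNS = {"microarray": "array_log2", "rnaseq": "rnaseq_log2",
                    "proteomics": "proteomics_log2"}


def _read_packaged_tsv(name: str) -> pd.DataFrame:
    ref = resources.files("promquant.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureError(f"{name}: checksum mismatch ({digest})")
    from io import BytesIO
    return pd.read_csv(BytesIO(raw), sep="\t")


def load_table1_fixture() -> pd.DataFrame:
    """Load and validate the candidate-promoter table.

    Returns a DataFrame with columns gene_id, gene_name, operon, function,
    array_log2, rnaseq_log2, proteomics_log2, ratio_log_phase, sd_log_phase,
    ratio_stationary, sd_stationary, strength_class.
    """
    t = _read_packaged_tsv("table1.tsv")
    if len(t) != 38:
        raise FixtureError(f"expected 38 rows, got {len(t)}")
    counts = t["strength_class"].value_counts().to_dict()
    if counts != _EXPECTED_CLASS_COUNTS:
        raise FixtureError(f"class counts {counts} != {_EXPECTED_CLASS_COUNTS}")
    null_omics = t[t["array_log2"].isna()]
    if list(null_omics["gene_id"]) != ["Po1721"]:
        raise FixtureError("exactly one row (Po1721) may lack omics values")
    if (t[["sd_log_phase", "sd_stationary"]] < 0).any().any():
        raise FixtureError("negative SD in fixture")
    return t


def load_table2_fixture() -> list[RBSDesign]:
    """Load the four synthetic RBS designs with predicted TIRs."""
    t = _read_packaged_tsv("table2.tsv")
    if len(t) != 4:
        raise FixtureError(f"expected 4 RBS designs, got {len(t)}")
    designs = [RBSDesign(name=r["name"], sequence=r["sequence"],
                         predicted_tir=float(r["predicted_tir"]))
               for _, r in t.iterrows()]
    tirs = sorted(d.predicted_tir for d in designs)
    if tirs != [10.0, 1000.0, 10000.0, 15000.0]:
        raise FixtureError(f"unexpected TIR set {tirs}")
    return designs
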