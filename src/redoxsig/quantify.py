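"""Site-level quantification across isobaric multiplexes.

Assembles per-plex reporter-ion crosstabs into one log2 site x sample
matrix, corrects redox intensities for protein-abundance/loading
differences using per-channel medians of the unenriched (global)
experiment, and estimates per-site oxidation occupancy from the pooled
total-thiol reference channels.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError, SchemaError

logger = logging.getLogger(__name__)

#: TMT18 reporter channel names in mass order.
TMT18_CHANNELS = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C",
    "131N", "131C", "132N", "132C", "133N", "133C", "134N", "134C", "135N",
)

ROLE_PARTICIPANT = "participant"
ROLE_TOTAL_THIOL = "total_thiol"
ROLE_UNUSED = "unused"

#: Default channel roles: 14 participant channels, two channels left out of
#: oxidation quantification (interference from the total-thiol tags), and two
#: pooled total-thiol reference channels.
DEFAULT_ROLES = {
    **{c: ROLE_PARTICIPANT for c in TMT18_CHANNELS[:14]},
    "133C": ROLE_UNUSED,
    "134N": ROLE_UNUSED,
    "134C": ROLE_TOTAL_THIOL,
    "135N": ROLE_TOTAL_THIOL,
}


@dataclass
class PlexDesign:
    """Mapping of one plex's channels to sample identities and roles.

    ``channels`` maps a TMT channel name to ``(sample_id, role)`` where role
    is one of ``participant``, ``total_thiol`` or ``unused``.
    """

    plex_id: str
    channels: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        roles = {ROLE_PARTICIPANT, ROLE_TOTAL_THIOL, ROLE_UNUSED}
        seen: set[str] = set()
        for ch, (sample_id, role) in self.channels.items():
            if role not in roles:
                raise DesignError(f"plex {self.plex_id}: unknown role {role!r} for channel {ch}")
            if role == ROLE_PARTICIPANT:
                if sample_id in seen:
                    raise DesignError(
                        f"plex {self.plex_id}: duplicate sample_id {sample_id!r}"
                    )
                seen.add(sample_id)

    def participant_channels(self) -> dict[str, str]:
        """Channel -> sample_id for participant-role channels."""
        return {c: s for c, (s, r) in self.channels.items() if r == ROLE_PARTICIPANT}

    def total_thiol_channels(self) -> list[str]:
        return [c for c, (_, r) in self.channels.items() if r == ROLE_TOTAL_THIOL]


@dataclass
class SiteQuantMatrix:
    """Log2 site x sample intensity matrix with missing values.

    ``data`` is a DataFrame keyed by site_id (protein entry name + 1-based
    Cys position, e.g. ``NEBU_C157``) with sample_id columns.  ``stage``
    records provenance: raw | abundance_corrected | batch_corrected | centered.
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][:5].tolist()
            raise SchemaError(f"duplicate site_id row keys: {dup}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][:5].tolist()
            raise SchemaError(f"duplicate sample_id column keys: {dup}")

    @property
    def n_sites(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def completeness(self) -> pd.Series:
        """Observed fraction per site across all sample columns."""
        return self.data.notna().mean(axis=1)


@dataclass
class NormalizationFactors:
    """Per-column abundance-correction terms (log2 domain).

    ``global_log2_median`` holds m_c per sample column; ``redox_mean_median``
    is the mean of the redox matrix's column medians (the overall scale that
    the correction preserves); ``correction`` is t_c = m_c - mean_c(m_c),
    which is subtracted from the matrix.  Mean of t_c over columns is 0.
    """

    global_log2_median: pd.Series
    redox_mean_median: float
    correction: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.correction = self.global_log2_median - self.global_log2_median.mean()


def protein_of(site_id: str) -> str:
    """Protein entry name of a site key like ``NEBU_C157`` or ``ACTN3_C490;494``."""
    return site_id.rsplit("_C", 1)[0]


def _resolve_columns(table: pd.DataFrame, design: PlexDesign) -> pd.DataFrame:
    """Rename a plex crosstab's columns to bare channel names.

    Accepts either bare channel names ("127N") or plex-prefixed names
    ("plex1_127N").  Unknown columns raise SchemaError.
    """
    renames = {}
    for col in table.columns:
        name = col
        prefix = f"{design.plex_id}_"
        if name.startswith(prefix):
            name = name[len(prefix):]
        if name not in design.channels:
            raise SchemaError(
                f"plex {design.plex_id}: channel column {col!r} not in design"
            )
        renames[col] = name
    return table.rename(columns=renames)


def assemble_matrix(
    tables: Mapping[str, pd.DataFrame],
    designs: Iterable[PlexDesign],
) -> SiteQuantMatrix:
    """Merge per-plex linear-scale crosstabs into one log2 site x sample matrix.

    Participant-role channels become sample columns; unused channels are
    dropped; total-thiol channels are excluded here (they feed occupancy
    estimation, not the quantification matrix).  Sites form the union across
    plexes; a site absent from a plex is missing in that plex's columns.
    Zero or negative intensities are recorded as missing before the log2
    transform.
    """
    designs = list(designs)
    by_id = {d.plex_id: d for d in designs}
    if set(by_id) != set(tables):
        raise DesignError(
            f"plex ids differ between tables ({sorted(tables)}) and designs ({sorted(by_id)})"
        )
    seen_samples: set[str] = set()
    pieces = []
    for plex_id in sorted(tables):
        design = by_id[plex_id]
        table = _resolve_columns(tables[plex_id], design)
        part = design.participant_channels()
        dup = seen_samples.intersection(part.values())
        if dup:
            raise DesignError(f"duplicate sample_id across plexes: {sorted(dup)}")
        seen_samples.update(part.values())
        sub = table[[c for c in table.columns if c in part]].rename(columns=part)
        sub = sub.where(sub > 0)  # nonpositive -> missing
        pieces.append(np.log2(sub))
    merged = pd.concat(pieces, axis=1, join="outer")
    merged = merged.sort_index(axis=0)
    return SiteQuantMatrix(merged, stage="raw")


def abundance_correct(
    redox: SiteQuantMatrix,
    global_medians: Mapping[str, float],
) -> tuple[SiteQuantMatrix, NormalizationFactors]:
    """Correct redox log2 intensities for protein-abundance/loading shifts.

    The per-channel medians of the unenriched global experiment are scaled to
    the average median intensity of the redox data and used to center the
    corresponding redox channels.  In the log2 domain this is
    ``x'_ic = x_ic - t_c`` with ``t_c = m_c - mean_c(m_c)``, which preserves
    the overall redox scale (the mean of the column medians is unchanged).
    """
    missing = [c for c in redox.data.columns if c not in global_medians]
    if missing:
        raise SchemaError(f"no global median for columns: {missing}")
    bad = [c for c in redox.data.columns if not global_medians[c] > 0]
    if bad:
        raise SchemaError(f"nonpositive global median for columns: {bad}")
    m = pd.Series(
        {c: np.log2(global_medians[c]) for c in redox.data.columns}, dtype=float
    )
    factors = NormalizationFactors(
        global_log2_median=m,
        redox_mean_median=float(redox.data.median(axis=0).mean()),
    )
    corrected = redox.data.sub(factors.correction, axis=1)
    return SiteQuantMatrix(corrected, stage="abundance_corrected"), factors


def sum_peptides_to_sites(peptides: pd.DataFrame, site_col: str = "site_id") -> pd.DataFrame:
    """Sum linear-scale peptide-level rows to site-level rows.

    Helper for inputs one level below the site-centric crosstab: rows sharing
    a site key have their linear intensities summed per channel (missing
    treated as absent, not zero: a site x channel cell with no observed
    peptide stays missing).
    """
    grouped = peptides.groupby(site_col)
    summed = grouped.sum(min_count=1)
    return summed


def estimate_occupancy(
    tables: Mapping[str, pd.DataFrame],
    designs: Iterable[PlexDesign],
) -> pd.DataFrame:
    """Estimate per-site oxidation occupancy (%) from total-thiol channels.

    Per plex: occupancy% = 100 x (mean linear oxidized intensity over
    participant channels) / (mean linear intensity over the two total-thiol
    channels), clipped to [0, 100].  The study value is the mean over plexes
    where both quantities are observed.  This ratio-of-means definition is a
    documented stand-in for the occupancy estimator of the upstream
    enrichment workflow; outputs are flagged accordingly by the pipeline.

    Returns a DataFrame indexed by site_id with one ``occ_<plex>`` column per
    plex and an ``occ_avg`` column.
    """
    designs = list(designs)
    by_id = {d.plex_id: d for d in designs}
    per_plex = {}
    for plex_id in sorted(tables):
        design = by_id[plex_id]
        table = _resolve_columns(tables[plex_id], design)
        part_channels = [c for c in table.columns if c in design.participant_channels()]
        tt_channels = [c for c in table.columns if c in design.total_thiol_channels()]
        if not tt_channels:
            raise DesignError(f"plex {plex_id}: no total-thiol channels present")
        oxid = table[part_channels].where(table[part_channels] > 0)
        tt = table[tt_channels].where(table[tt_channels] > 0)
        ox_mean = oxid.mean(axis=1)
        tt_mean = tt.mean(axis=1)
        occ = 100.0 * ox_mean / tt_mean
        occ[tt_mean.isna()] = np.nan
        per_plex[f"occ_{plex_id}"] = occ.clip(0.0, 100.0)
    out = pd.DataFrame(per_plex).sort_index()
    out["occ_avg"] = out.mean(axis=1)
    return out
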