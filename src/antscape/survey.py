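"""Nested nest-survey densities: recording groups, pseudo-areas, site pooling.

The survey design is a nested plot ("Seifert-plot") with three search levels:
an intensive scrutiny search (S, fixed 64 m2), a quick search over a larger
area (Q, fixed 400 m2), and spot inspections of promising microhabitats in the
surroundings (SI, roughly 900 m2). Species differ in how perceptible their
nests are at each level, which is encoded by *recording groups*: per-level
detection weights in [0, 1]. The detectability-weighted searched area of a
plot for a given group is its *pseudo-area* (in 100 m2 units); dividing a
species' summed nest count by the pseudo-area of its group yields an
integrated nest density per 100 m2 that is comparable across species with
different perceptibility.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LEVELS = ("S", "Q", "SI")


class SurveyError(ValueError):
    """Invalid survey input (bad group weights, missing species, duplicates)."""


@dataclass(frozen=True)
class RecordingGroup:
    """Detection weights per search level for one perceptibility class.

    Parameters
    ----------
    group_id : str
        Identifier, e.g. ``"conspicuous"``.
    w_S, w_Q, w_SI : float
        Probability of finding a nest of this group at each search level;
        each in [0, 1] and at least one strictly positive.
    """

    group_id: str
    w_S: float
    w_Q: float
    w_SI: float

    def __post_init__(self) -> None:
        w = (self.w_S, self.w_Q, self.w_SI)
        if any(not (0.0 <= x <= 1.0) for x in w):
            raise SurveyError(f"group {self.group_id!r}: weights must lie in [0, 1], got {w}")
        if all(x == 0.0 for x in w):
            raise SurveyError(f"group {self.group_id!r}: all level weights are zero")

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.w_S, self.w_Q, self.w_SI)


@dataclass
class SeifertPlot:
    """One nested survey unit with per-species nest counts per search level.

    ``counts`` maps species to an (n_S, n_Q, n_SI) triple of non-negative
    integers. Areas are in m2; S and Q areas are fixed by the protocol
    (64 and 400 m2), SI areas vary around 900 m2.
    """

    plot_id: str
    site_id: str
    area_S: float = 64.0
    area_Q: float = 400.0
    area_SI: float = 900.0
    counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.area_S, self.area_Q, self.area_SI) <= 0:
            raise SurveyError(f"plot {self.plot_id!r}: areas must be positive")
        if self.area_S > self.area_Q:
            raise SurveyError(f"plot {self.plot_id!r}: S area exceeds Q area")
        for sp, triple in self.counts.items():
            if len(triple) != 3 or any(int(c) != c or c < 0 for c in triple):
                raise SurveyError(
                    f"plot {self.plot_id!r}, species {sp!r}: counts must be "
                    f"non-negative integers per level, got {triple}"
                )

    @property
    def areas(self) -> tuple[float, float, float]:
        return (self.area_S, self.area_Q, self.area_SI)

    def total_count(self, species: str) -> int:
        return int(sum(self.counts.get(species, (0, 0, 0))))


@dataclass
class SpeciesCatalog:
    """Maps each species to its recording group."""

    groups: dict[str, RecordingGroup]
    assignment: dict[str, str]  # species -> group_id

    def __post_init__(self) -> None:
        for sp, gid in self.assignment.items():
            if gid not in self.groups:
                raise SurveyError(f"species {sp!r} assigned to unknown group {gid!r}")

    def group_of(self, species: str) -> RecordingGroup:
        try:
            return self.groups[self.assignment[species]]
        except KeyError:
            raise SurveyError(f"species {species!r} has no recording-group assignment") from None

    @property
    def species(self) -> list[str]:
        return list(self.assignment)


#: Illustrative default groups. These are placeholders spanning the
#: plausible detectability spectrum, not published calibration values;
#: real analyses should supply their own recording_groups.csv.
DEFAULT_GROUPS = {
    "conspicuous": RecordingGroup("conspicuous", 1.0, 1.0, 1.0),
    "intermediate": RecordingGroup("intermediate", 1.0, 1.0, 0.0),
    "cryptic": RecordingGroup("cryptic", 1.0, 0.0, 0.0),
}


def pseudo_area(plot: SeifertPlot, group: RecordingGroup) -> float:
    """Detectability-weighted searched area of `plot` for `group`, in 100 m2.

    pseudo_area = (w_S * A_S + w_Q * A_Q + w_SI * A_SI) / 100
    """
    pa = (
        group.w_S * plot.area_S + group.w_Q * plot.area_Q + group.w_SI * plot.area_SI
    ) / 100.0
    # group validation guarantees positivity, but guard against degenerate areas
    if pa <= 0:
        raise SurveyError(f"non-positive pseudo-area for group {group.group_id!r}")
    return pa


def integrated_density(
    plots: Iterable[SeifertPlot], species: str, catalog: SpeciesCatalog
) -> float:
    """Integrated nest density of `species` over `plots`, nests per 100 m2.

    Sums nests over all levels and plots, and divides by the summed
    pseudo-area of the species' recording group over the same plots.
    """
    plots = list(plots)
    if not plots:
        raise SurveyError("at least one plot is required")
    group = catalog.group_of(species)
    total = sum(p.total_count(species) for p in plots)
    pa = sum(pseudo_area(p, group) for p in plots)
    return total / pa


def site_offset(
    plots: Iterable[SeifertPlot],
    catalog: SpeciesCatalog,
    mode: Literal["by_group", "by_species"] = "by_group",
) -> float:
    """Log mean pseudo-area for one site's plots (offset for count models).

    The pseudo-area of each recording group is summed over the site's plots;
    the offset is the natural log of the arithmetic mean of those sums.
    ``mode="by_group"`` averages over distinct recording groups (default;
    avoids weighting by species richness), ``mode="by_species"`` averages
    over catalog species (groups recur once per member species).
    """
    plots = list(plots)
    if not plots:
        raise SurveyError("at least one plot is required")
    if mode == "by_group":
        units: list[RecordingGroup] = list(catalog.groups.values())
    elif mode == "by_species":
        units = [catalog.group_of(sp) for sp in catalog.species]
    else:
        raise ValueError(f"unknown offset mode {mode!r}")
    sums = [sum(pseudo_area(p, g) for p in plots) for g in units]
    return math.log(float(np.mean(sums)))


@dataclass
class SiteDensityMatrix:
    """Sites x species integrated densities with matched raw counts and offsets.

    Attributes
    ----------
    density : DataFrame, sites x species, nests per 100 m2.
    raw_counts : DataFrame of identical shape, summed nest counts.
    offset : Series indexed by site, log mean pseudo-area (log 100 m2 units).
    empty_sites : list of site ids where no nest of any species was found;
        they stay in the matrix as all-zero rows but count models should
        exclude them.
    """

    density: pd.DataFrame
    raw_counts: pd.DataFrame
    offset: pd.Series
    empty_sites: list[str] = field(default_factory=list)

    @property
    def sites(self) -> list[str]:
        return list(self.density.index)

    @property
    def species(self) -> list[str]:
        return list(self.density.columns)

    def modeling_view(self) -> "SiteDensityMatrix":
        """Drop empty sites (degenerate likelihood contributions)."""
        keep = [s for s in self.sites if s not in set(self.empty_sites)]
        return SiteDensityMatrix(
            density=self.density.loc[keep],
            raw_counts=self.raw_counts.loc[keep],
            offset=self.offset.loc[keep],
            empty_sites=[],
        )


def pool_site_matrix(
    plots: Iterable[SeifertPlot],
    catalog: SpeciesCatalog,
    offset_mode: Literal["by_group", "by_species"] = "by_group",
) -> SiteDensityMatrix:
    """Pool plots per site into a site-by-species density matrix with offsets."""
    plots = list(plots)
    if not plots:
        raise SurveyError("no plots supplied")
    by_site: dict[str, list[SeifertPlot]] = {}
    for p in plots:
        by_site.setdefault(p.site_id, []).append(p)

    observed = sorted({sp for p in plots for sp in p.counts})
    for sp in observed:
        catalog.group_of(sp)  # raises on missing assignment

    sites = sorted(by_site)
    dens = np.zeros((len(sites), len(observed)))
    raw = np.zeros((len(sites), len(observed)), dtype=int)
    offs = np.zeros(len(sites))
    empty: list[str] = []
    for i, site in enumerate(sites):
        site_plots = by_site[site]
        for j, sp in enumerate(observed):
            raw[i, j] = sum(p.total_count(sp) for p in site_plots)
            dens[i, j] = integrated_density(site_plots, sp, catalog)
        offs[i] = site_offset(site_plots, catalog, mode=offset_mode)
        if raw[i].sum() == 0:
            empty.append(site)
            logger.warning("site %s has no nests; retained in densities, flag for models", site)

    return SiteDensityMatrix(
        density=pd.DataFrame(dens, index=sites, columns=observed),
        raw_counts=pd.DataFrame(raw, index=sites, columns=observed),
        offset=pd.Series(offs, index=sites, name="log_mean_pseudo_area"),
        empty_sites=empty,
    )


# ---------------------------------------------------------------------------
# CSV interfaces


def read_recording_groups(path) -> dict[str, RecordingGroup]:
    """Read recording_groups.csv with columns group_id, w_S, w_Q, w_SI."""
    df = pd.read_csv(path)
    _require_columns(df, ["group_id", "w_S", "w_Q", "w_SI"], path)
    return {
        str(r.group_id): RecordingGroup(str(r.group_id), float(r.w_S), float(r.w_Q), float(r.w_SI))
        for r in df.itertuples()
    }


def read_species_catalog(path, groups: Mapping[str, RecordingGroup]) -> SpeciesCatalog:
    """Read species_catalog.csv with columns species, group_id."""
    df = pd.read_csv(path)
    _require_columns(df, ["species", "group_id"], path)
    return SpeciesCatalog(dict(groups), {str(r.species): str(r.group_id) for r in df.itertuples()})


def read_plots(path) -> list[SeifertPlot]:
    """Read long-format plots.csv: plot_id, site_id, area_S, area_Q, area_SI, species, level, count."""
    df = pd.read_csv(path)
    _require_columns(
        df, ["plot_id", "site_id", "area_S", "area_Q", "area_SI", "species", "level", "count"], path
    )
    bad = ~df["level"].isin(LEVELS)
    if bad.any():
        raise SurveyError(f"{path}: invalid level values {sorted(df.loc[bad, 'level'].unique())}")
    dup = df.duplicated(subset=["plot_id", "species", "level"], keep=False)
    if dup.any():
        rows = df.loc[dup, ["plot_id", "species", "level"]].drop_duplicates()
        raise SurveyError(f"{path}: duplicated (plot, species, level) records:\n{rows}")
    plots = []
    for (pid, sid, a_s, a_q, a_si), grp in df.groupby(
        ["plot_id", "site_id", "area_S", "area_Q", "area_SI"], sort=True
    ):
        counts: dict[str, list[int]] = {}
        for r in grp.itertuples():
            if str(r.species) == "__none__":  # placeholder row keeping empty plots visible
                continue
            counts.setdefault(str(r.species), [0, 0, 0])[LEVELS.index(r.level)] = int(r.count)
        plots.append(
            SeifertPlot(
                plot_id=str(pid),
                site_id=str(sid),
                area_S=float(a_s),
                area_Q=float(a_q),
                area_SI=float(a_si),
                counts={sp: tuple(c) for sp, c in counts.items()},
            )
        )
    return plots


def write_matrix(matrix: SiteDensityMatrix, densities_path, offsets_path) -> None:
    matrix.density.rename_axis("site").to_csv(densities_path)
    matrix.offset.rename_axis("site").to_frame().to_csv(offsets_path)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SurveyError(f"{path}: missing required columns {missing}")
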