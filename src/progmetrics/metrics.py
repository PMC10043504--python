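"""Registry of OCT and visual-field summary metrics.

Every stage of the pipeline is indexed by these metrics: circumpapillary
RNFL thickness from the 3.5-mm circle scan (7 sectors), Bruch's membrane
opening minimum rim width from radial disc scans (7 sectors), macular
ganglion cell layer thickness from the posterior-pole cube (7 regions),
and the global/hemifield indices of 24-2 and 10-2 standard automated
perimetry (MD, PSD, VFI, supMD, infMD).

Each metric carries a *direction of worsening*: thicknesses, MD, supMD,
infMD and VFI fall with glaucomatous damage while PSD rises with localized
damage.  Classifiers always operate on the worsening tail unless the
``paper_literal`` switch forces the lower/negative tail for every metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache


class Modality(str, Enum):
    """Instrument/scan source of a summary metric."""

    CPRNFL = "cpRNFL_3.5"   # circumpapillary RNFL, 3.5-mm circle scan
    BMO_MRW = "BMO_MRW"     # Bruch's membrane opening minimum rim width
    GCL = "GCL"             # macular ganglion cell layer, cube scan
    VF_24_2 = "VF_24_2"     # 24-2 standard automated perimetry
    VF_10_2 = "VF_10_2"     # 10-2 standard automated perimetry


class Direction(str, Enum):
    """Direction in which a metric moves as damage progresses."""

    DECREASE = "decrease"
    INCREASE = "increase"


#: Optic-disc sectors: global, temporal, temporal-inferior, temporal-superior,
#: nasal, nasal-inferior, nasal-superior.
DISC_SECTORS = ("G", "T", "TI", "TS", "N", "NI", "NS")

#: Macular GCL regions: global, inferior, temporal-inferior, nasal-inferior,
#: superior, temporal-superior, nasal-superior.
GCL_SECTORS = ("G", "I", "TI", "NI", "S", "TS", "NS")


@dataclass(frozen=True)
class MetricId:
    """Identity of one summary metric.

    ``name`` is the short key used throughout CSV files and rule
    expressions (e.g. ``"G_small"``, ``"TI_GCL"``, ``"MD_24"``).
    """

    name: str
    modality: Modality
    sector: str
    direction: Direction
    units: str

    @property
    def is_vf(self) -> bool:
        return self.modality in (Modality.VF_24_2, Modality.VF_10_2)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def _build_registry() -> dict[str, MetricId]:
    reg: dict[str, MetricId] = {}

    def add(m: MetricId) -> None:
        reg[m.name] = m

    for s in DISC_SECTORS:
        add(MetricId(f"{s}_small", Modality.CPRNFL, s, Direction.DECREASE, "µm"))
    for s in DISC_SECTORS:
        add(MetricId(f"{s}_MRW", Modality.BMO_MRW, s, Direction.DECREASE, "µm"))
    for s in GCL_SECTORS:
        add(MetricId(f"{s}_GCL", Modality.GCL, s, Direction.DECREASE, "µm"))

    for pat, mod in (("24", Modality.VF_24_2), ("10", Modality.VF_10_2)):
        add(MetricId(f"MD_{pat}", mod, "global", Direction.DECREASE, "dB"))
        add(MetricId(f"supMD_{pat}", mod, "sup", Direction.DECREASE, "dB"))
        add(MetricId(f"infMD_{pat}", mod, "inf", Direction.DECREASE, "dB"))
        add(MetricId(f"PSD_{pat}", mod, "global", Direction.INCREASE, "dB"))
    add(MetricId("VFI_24", Modality.VF_24_2, "global", Direction.DECREASE, "%"))

    return reg


@lru_cache(maxsize=1)
def builtin_metrics() -> dict[str, MetricId]:
    """The closed registry of the 30 built-in summary metrics."""
    return _build_registry()


def get_metric(name: str) -> MetricId:
    """Resolve a metric name, raising ``KeyError`` with the offending string."""
    reg = builtin_metrics()
    if name not in reg:
        raise KeyError(f"unknown metric name: {name!r}")
    return reg[name]


def metric_names() -> list[str]:
    return list(builtin_metrics())


def vf_metric_names() -> list[str]:
    return [n for n, m in builtin_metrics().items() if m.is_vf]


def oct_metric_names() -> list[str]:
    return [n for n, m in builtin_metrics().items() if not m.is_vf]
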