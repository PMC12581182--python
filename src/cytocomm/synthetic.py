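"""Synthetic spectral-cytometry cohorts with known ground truth.

The generator emulates the statistical structure of a small lymphoma
tumor-microenvironment study: a few samples per group (control lymph node
vs. DLBCL biopsy), 20-30 markers, group-dependent metacluster abundances
with rare disease-enriched follicular clusters, cross-sample ligand-receptor
coupling driven by a shared per-sample latent factor, and acquisition
artefacts (doublets, dead cells, time-window anomalies).

Cells are drawn i.i.d. Gaussian per metacluster on the logicle-transformed
scale and mapped to raw intensities through the exact inverse transform;
transformed-scale normality is the standard working assumption for cytometry
clustering.  Identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import EventMatrix, normalize_marker
from .preprocess import LogicleTransform, TransformParams

__all__ = [
    "MetaclusterSpec",
    "LRCouplingSpec",
    "ArtefactSettings",
    "CohortSpec",
    "SyntheticCohort",
    "simulate_cohort",
    "inject_lr_coupling",
    "inject_time_anomaly",
    "default_cohort_spec",
]

TIME_CHANNEL = "Time"
VIABILITY_CHANNEL = "Viability"

# transformed-scale anchors: logicle(0)=0.25 with (w=0.5, t=1e4, m=2, a=0)
BASELINE = 0.25


@dataclass
class MetaclusterSpec:
    """One ground-truth population: per-group mixing proportion and
    per-marker Gaussian location/scale on the transformed scale."""

    name: str
    proportions: dict[str, float]
    means: dict[str, float]
    sds: dict[str, float] = field(default_factory=dict)
    default_mean: float = BASELINE
    default_sd: float = 0.05

    def __post_init__(self):
        self.means = {normalize_marker(k): v for k, v in self.means.items()}
        self.sds = {normalize_marker(k): v for k, v in self.sds.items()}
        for g, p in self.proportions.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{self.name}: proportion for {g} not in [0,1]")
        if self.default_sd <= 0 or any(s <= 0 for s in self.sds.values()):
            raise ValueError(f"{self.name}: standard deviations must be > 0")

    def mean(self, marker: str) -> float:
        return self.means.get(normalize_marker(marker), self.default_mean)

    def sd(self, marker: str) -> float:
        return self.sds.get(normalize_marker(marker), self.default_sd)


@dataclass
class LRCouplingSpec:
    """A cross-sample ligand-receptor coupling.

    A per-sample latent factor ``u_s ~ N(0,1)`` shifts the ligand marker of
    the sender population by ``beta * u_s`` and the receptor marker of the
    receiver population by ``beta * u_s`` (linear) or
    ``beta * (u_s**2 - 1)`` (quadratic; centred so the across-sample linear
    correlation is zero by construction).  Shifts act on the transformed
    scale; ``noise_sd`` adds independent per-sample noise to each side.
    """

    sender: str
    ligand: str
    receiver: str
    receptor: str
    link: str = "linear"
    beta: float = 0.15
    noise_sd: float = 0.02

    def __post_init__(self):
        self.ligand = normalize_marker(self.ligand)
        self.receptor = normalize_marker(self.receptor)
        if self.link not in ("linear", "quadratic", "none"):
            raise ValueError(f"unknown link shape {self.link!r}")
        if self.beta < 0:
            raise ValueError("effect size beta must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class ArtefactSettings:
    """Acquisition artefacts: doublet/dead fractions and clog-like
    time-window shifts (window as fractions of the run, shift in raw
    intensity units applied to all marker channels)."""

    doublet_fraction: float = 0.0
    dead_fraction: float = 0.0
    time_anomaly_windows: list[tuple[float, float, float]] = field(
        default_factory=list
    )

    def __post_init__(self):
        for frac, nm in ((self.doublet_fraction, "doublet"),
                         (self.dead_fraction, "dead")):
            if not 0 <= frac <= 1:
                raise ValueError(f"{nm} fraction must lie in [0,1]")
        for w in self.time_anomaly_windows:
            if not (0 <= w[0] < w[1] <= 1):
                raise ValueError(f"bad anomaly window {w}")


@dataclass
class CohortSpec:
    """Full recipe for a synthetic cohort."""

    groups: list[tuple[str, int]]
    cells_per_sample: int
    markers: list[str]
    metaclusters: list[MetaclusterSpec]
    lr_couplings: list[LRCouplingSpec] = field(default_factory=list)
    artefacts: ArtefactSettings = field(default_factory=ArtefactSettings)
    seed: int = 0
    transform: TransformParams = field(default_factory=TransformParams)
    run_duration: float = 1000.0

    def __post_init__(self):
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        if self.cells_per_sample <= 0:
            raise ValueError("cells_per_sample must be positive")
        self.markers = [normalize_marker(m) for m in self.markers]
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        names = [mc.name for mc in self.metaclusters]
        if len(set(names)) != len(names):
            raise ValueError("metacluster names must be unique")
        for g, _ in self.groups:
            tot = sum(mc.proportions.get(g, 0.0) for mc in self.metaclusters)
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(
                    f"metacluster proportions for group {g!r} sum to {tot}, not 1"
                )
        for c in self.lr_couplings:
            for marker in (c.ligand, c.receptor):
                if marker not in self.markers:
                    raise ValueError(
                        f"coupling marker {marker!r} not in the marker list"
                    )
            for pop in (c.sender, c.receiver):
                if pop not in names:
                    raise ValueError(f"coupling population {pop!r} unknown")

    def sample_ids(self) -> list[str]:
        return [f"{g}_{i + 1}" for g, n in self.groups for i in range(n)]

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["transform"] = asdict(self.transform)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["groups"] = [tuple(g) for g in doc["groups"]]
        doc["metaclusters"] = [MetaclusterSpec(**m) for m in doc["metaclusters"]]
        doc["lr_couplings"] = [
            LRCouplingSpec(**c) for c in doc.get("lr_couplings", [])
        ]
        art = doc.get("artefacts", {})
        art["time_anomaly_windows"] = [
            tuple(w) for w in art.get("time_anomaly_windows", [])
        ]
        doc["artefacts"] = ArtefactSettings(**art)
        doc["transform"] = TransformParams(**doc.get("transform", {}))
        return cls(**doc)


@dataclass
class SyntheticCohort:
    """Generated cohort: events per sample, per-cell truth table, sample
    sheet and per-sample latent LR factors."""

    spec: CohortSpec
    events: dict[str, EventMatrix]
    truth: pd.DataFrame
    sample_sheet: pd.DataFrame
    latent: pd.DataFrame

    def truth_for(self, sample_id: str) -> pd.DataFrame:
        return (
            self.truth[self.truth["sample_id"] == sample_id]
            .reset_index(drop=True)
        )

    def write(self, outdir, dialect: str = "csv") -> pd.DataFrame:
        """Write events, truth table, sample sheet and spec to ``outdir``."""
        from pathlib import Path
        from .io import write_events

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ext = "fcs" if dialect == "fcs3" else "csv"
        sheet = self.sample_sheet.copy()
        paths = []
        for sid in self.events:
            p = outdir / f"{sid}.{ext}"
            write_events(self.events[sid], p, dialect=dialect)
            paths.append(str(p))
        sheet["path"] = paths
        sheet.to_csv(outdir / "sample_sheet.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)
        self.latent.to_csv(outdir / "latent.csv", index=False)
        self.spec.to_yaml(outdir / "cohort_spec.yaml")
        return sheet


def _coupling_shifts(
    spec: CohortSpec, rng: np.random.Generator, sample_ids: Sequence[str]
) -> tuple[pd.DataFrame, dict]:
    """Draw latent factors and per-sample transformed-scale shifts for every
    coupling.  Returns (latent table, {(sample, pop, marker): shift})."""
    rows = []
    shifts: dict[tuple[str, str, str], float] = {}
    for ci, c in enumerate(spec.lr_couplings):
        u = rng.standard_normal(len(sample_ids))
        eps_l = rng.standard_normal(len(sample_ids)) * c.noise_sd
        eps_r = rng.standard_normal(len(sample_ids)) * c.noise_sd
        for si, sid in enumerate(sample_ids):
            if c.link == "none":
                lig_shift = rec_shift = 0.0
            else:
                lig_shift = c.beta * u[si] + eps_l[si]
                drive = u[si] if c.link == "linear" else (u[si] ** 2 - 1.0)
                rec_shift = c.beta * drive + eps_r[si]
            key_l = (sid, c.sender, c.ligand)
            key_r = (sid, c.receiver, c.receptor)
            shifts[key_l] = shifts.get(key_l, 0.0) + lig_shift
            shifts[key_r] = shifts.get(key_r, 0.0) + rec_shift
            rows.append(
                {
                    "coupling": ci,
                    "sample_id": sid,
                    "sender": c.sender,
                    "ligand": c.ligand,
                    "receiver": c.receiver,
                    "receptor": c.receptor,
                    "link": c.link,
                    "u": u[si],
                    "ligand_shift": lig_shift,
                    "receptor_shift": rec_shift,
                }
            )
    return pd.DataFrame(rows), shifts


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the cohort described by ``spec``.

    Raw intensities are the inverse-logicle image of Gaussian draws on the
    transformed scale; doublets are channel-wise sums of two random cells;
    dead cells get a high viability-channel shift; clog-like anomalies add a
    raw-scale offset inside their time window.  Everything is recorded in the
    per-cell truth table.
    """
    rng = np.random.default_rng(spec.seed)
    tr = LogicleTransform(spec.transform)
    markers = spec.markers
    m_idx = {m: j for j, m in enumerate(markers)}
    has_viab = VIABILITY_CHANNEL in markers

    sample_ids = spec.sample_ids()
    latent, shifts = _coupling_shifts(spec, rng, sample_ids)

    events: dict[str, EventMatrix] = {}
    truth_rows: list[pd.DataFrame] = []
    sheet_rows = []
    for (group, n_samples) in spec.groups:
        for rep in range(n_samples):
            sid = f"{group}_{rep + 1}"
            n = spec.cells_per_sample
            props = np.array(
                [mc.proportions.get(group, 0.0) for mc in spec.metaclusters]
            )
            counts = rng.multinomial(n, props)
            X = np.empty((n, len(markers)))
            labels = np.empty(n, dtype=object)
            pos = 0
            for mc, cnt in zip(spec.metaclusters, counts):
                if cnt == 0:
                    continue
                mu = np.array([mc.mean(m) for m in markers])
                sd = np.array([mc.sd(m) for m in markers])
                for m in markers:
                    key = (sid, mc.name, m)
                    if key in shifts:
                        mu[m_idx[m]] += shifts[key]
                block = mu + sd * rng.standard_normal((cnt, len(markers)))
                X[pos : pos + cnt] = block
                labels[pos : pos + cnt] = mc.name
                pos += cnt
            order = rng.permutation(n)
            X, labels = X[order], labels[order]

            doublet = np.zeros(n, dtype=bool)
            if spec.artefacts.doublet_fraction > 0:
                doublet = rng.random(n) < spec.artefacts.doublet_fraction
            dead = np.zeros(n, dtype=bool)
            if spec.artefacts.dead_fraction > 0:
                dead = rng.random(n) < spec.artefacts.dead_fraction

            raw = tr.inverse(X)
            if doublet.any():
                partners = rng.integers(0, n, size=int(doublet.sum()))
                raw[doublet] = raw[doublet] + raw[partners]
            if dead.any() and has_viab:
                # dead cells take up viability dye: strong transformed shift
                viab_hi = tr.inverse(X[dead, m_idx[VIABILITY_CHANNEL]] + 0.45)
                raw[dead, m_idx[VIABILITY_CHANNEL]] = viab_hi

            t = np.sort(rng.random(n)) * spec.run_duration
            anomaly = np.zeros(n, dtype=bool)
            values = np.column_stack([raw, t])
            em = EventMatrix(
                sample_id=sid,
                channels=markers + [TIME_CHANNEL],
                values=values,
                time_channel=TIME_CHANNEL,
                metadata={"CYTOCOMM_SEED": str(spec.seed), "GROUP": group},
            )
            for (w0, w1, shift) in spec.artefacts.time_anomaly_windows:
                em, mask = inject_time_anomaly(
                    em,
                    (w0 * spec.run_duration, w1 * spec.run_duration),
                    shift,
                )
                anomaly |= mask

            lab = pd.DataFrame(
                {
                    "sample_id": sid,
                    "cell": np.arange(n),
                    "metacluster": labels,
                    "doublet": doublet,
                    "dead": dead,
                    "anomaly": anomaly,
                }
            )
            em.labels = lab
            events[sid] = em
            truth_rows.append(lab)
            sheet_rows.append({"sample_id": sid, "group": group, "path": ""})

    return SyntheticCohort(
        spec=spec,
        events=events,
        truth=pd.concat(truth_rows, ignore_index=True),
        sample_sheet=pd.DataFrame(sheet_rows),
        latent=latent,
    )


def inject_lr_coupling(
    cohort: SyntheticCohort, coupling: LRCouplingSpec, seed: int
) -> SyntheticCohort:
    """Apply one ligand-receptor coupling to an existing cohort.

    Shifts act on the transformed scale (transform, shift, invert back).
    ``link='none'`` is a no-op.  Returns a new cohort; the input is unchanged.
    """
    names = {mc.name for mc in cohort.spec.metaclusters}
    for pop in (coupling.sender, coupling.receiver):
        if pop not in names:
            raise ValueError(f"unknown population {pop!r}")
    for mk in (coupling.ligand, coupling.receptor):
        if mk not in cohort.spec.markers:
            raise ValueError(f"unknown marker {mk!r}")

    rng = np.random.default_rng(seed)
    sample_ids = list(cohort.events)
    u = rng.standard_normal(len(sample_ids))
    eps_l = rng.standard_normal(len(sample_ids)) * coupling.noise_sd
    eps_r = rng.standard_normal(len(sample_ids)) * coupling.noise_sd
    tr = LogicleTransform(cohort.spec.transform)

    new_events = {}
    lat_rows = []
    for si, sid in enumerate(sample_ids):
        em = cohort.events[sid]
        if coupling.link == "none":
            lig_shift = rec_shift = 0.0
            new_events[sid] = em
        else:
            lig_shift = coupling.beta * u[si] + eps_l[si]
            drive = u[si] if coupling.link == "linear" else (u[si] ** 2 - 1.0)
            rec_shift = coupling.beta * drive + eps_r[si]
            values = em.values.copy()
            mc_lab = em.labels["metacluster"].to_numpy()
            for pop, marker, shift in (
                (coupling.sender, coupling.ligand, lig_shift),
                (coupling.receiver, coupling.receptor, rec_shift),
            ):
                j = em.channel_index(marker)
                rows = mc_lab == pop
                if rows.any():
                    values[rows, j] = tr.inverse(
                        tr.forward(values[rows, j]) + shift
                    )
            new_events[sid] = em.with_values(values)
        lat_rows.append(
            {
                "coupling": -1,
                "sample_id": sid,
                "sender": coupling.sender,
                "ligand": coupling.ligand,
                "receiver": coupling.receiver,
                "receptor": coupling.receptor,
                "link": coupling.link,
                "u": u[si],
                "ligand_shift": lig_shift,
                "receptor_shift": rec_shift,
            }
        )
    latent = pd.concat(
        [cohort.latent, pd.DataFrame(lat_rows)], ignore_index=True
    )
    return SyntheticCohort(
        spec=cohort.spec,
        events=new_events,
        truth=cohort.truth,
        sample_sheet=cohort.sample_sheet,
        latent=latent,
    )


def inject_time_anomaly(
    events: EventMatrix,
    window: tuple[float, float],
    shift,
) -> tuple[EventMatrix, np.ndarray]:
    """Shift all marker channels of events inside a time window.

    ``shift`` is a raw-intensity offset: a scalar applied to every marker
    channel, or a mapping marker -> offset.  Returns the shifted matrix and
    the boolean mask of affected events (also recorded in ``labels`` when
    present).
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("empty anomaly window")
    t = events.channel(events.time_channel)
    if t0 > t.max() or t1 < t.min():
        raise ValueError("anomaly window outside the acquisition-time range")
    mask = (t >= t0) & (t <= t1)
    values = events.values.copy()
    if np.isscalar(shift):
        offsets = {m: float(shift) for m in events.marker_channels}
    else:
        offsets = {normalize_marker(k): float(v) for k, v in shift.items()}
    for marker, off in offsets.items():
        if off != 0.0:
            values[mask, events.channel_index(marker)] += off
    out = events.with_values(values)
    if out.labels is not None:
        lab = out.labels.copy()
        if "anomaly" not in lab.columns:
            lab["anomaly"] = False
        lab.loc[mask, "anomaly"] = True
        out.labels = lab
    return out, mask


# ---------------------------------------------------------------------------
# Default study-shaped cohort
# ---------------------------------------------------------------------------

# clustering markers used by the study's SOM step
CLUSTERING_MARKERS = [
    "CXCR5", "HLA-DR", "CD127", "TIGIT", "CD45RA", "CD28", "OX40", "CD137",
    "CCR7", "ICOS", "FAS", "CCR4", "CD25", "PD1", "CD69", "TIM3", "LAG3",
    "CXCR3", "BTLA", "CD40L", "CTLA4", "CCR6",
]
# ligand-side markers carried by the TME-like populations in the same panel
LIGAND_MARKERS = ["ICOSL", "CD80", "PDL2"]

HI, MID, LO = 0.70, 0.45, BASELINE


def default_cohort_spec(
    seed: int = 0,
    cells_per_sample: int = 3000,
    n_control: int = 4,
    n_dlbcl: int = 5,
    doublet_fraction: float = 0.02,
    dead_fraction: float = 0.03,
    couple_icos: bool = True,
) -> CohortSpec:
    """Cohort mirroring the study design: 4 control LN + 5 DLBCL samples,
    follicular CD8 clusters enriched in DLBCL, a lymphoma-B-like receiver
    population, and one ICOS->ICOSL linear coupling."""
    markers = CLUSTERING_MARKERS + LIGAND_MARKERS + [VIABILITY_CHANNEL]

    def mc(name, p_ln, p_dl, hi=(), mid=(), sd=None):
        means = {m: HI for m in hi}
        means.update({m: MID for m in mid})
        return MetaclusterSpec(
            name=name,
            proportions={"LN": p_ln, "DLBCL": p_dl},
            means=means,
            sds=sd or {},
        )

    metaclusters = [
        mc("naive", 0.40, 0.12, hi=("CD45RA", "CCR7", "CD127", "CD28")),
        mc("cxcr3_mem", 0.22, 0.08, hi=("CXCR3", "CD28"), mid=("CD69",)),
        mc("effector_mem", 0.23, 0.28, hi=("FAS", "CD69"), mid=("PD1", "TIGIT")),
        mc(
            "mc09_follicular",
            0.01,
            0.14,
            hi=("CXCR5", "PD1", "HLA-DR", "CTLA4", "CD69", "ICOS"),
            mid=("TIGIT",),
        ),
        mc(
            "mc11_follicular",
            0.01,
            0.10,
            hi=("CXCR5", "PD1", "CTLA4", "CD69"),
            mid=("TIGIT", "ICOS"),
        ),
        mc(
            "lymphoma_b",
            0.13,
            0.28,
            hi=("HLA-DR", "ICOSL", "CD80"),
            mid=("PDL2",),
        ),
    ]
    couplings = (
        [
            LRCouplingSpec(
                sender="mc09_follicular",
                ligand="ICOS",
                receiver="lymphoma_b",
                receptor="ICOSL",
                link="linear",
                beta=0.15,
                noise_sd=0.02,
            )
        ]
        if couple_icos
        else []
    )
    return CohortSpec(
        groups=[("LN", n_control), ("DLBCL", n_dlbcl)],
        cells_per_sample=cells_per_sample,
        markers=markers,
        metaclusters=metaclusters,
        lr_couplings=couplings,
        artefacts=ArtefactSettings(
            doublet_fraction=doublet_fraction, dead_fraction=dead_fraction
        ),
        seed=seed,
    )
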