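"""Synthetic cohort tables and microscope z-stacks with known ground truth.

Two generators stand in for the study material:

``generate_cohort``
    Per-cell foci-count tables for a two-group cohort (healthy individuals,
    HI, and rectal cancer patients, RC) under the three exposure conditions.
    Each individual carries a latent per-condition foci rate drawn from a
    positive-truncated Gaussian around the group mean; cell counts are
    Poisson or negative-binomial around that rate.  A configurable fraction
    of individuals is planted as radiosensitivity outliers whose rate is
    multiplied on the conditions their class affects (preexisting only,
    both, or remaining only).  The planted truth is returned alongside the
    records; no downstream module may read it except tests.

``generate_zstack``
    A two-channel five-plane fluorescence z-stack (DAPI nuclei, gammaH2AX
    immunostain) rendered from an explicit geometric truth: nuclei as
    smooth bright disks (apoptotic nuclei as clusters of small fragments),
    each gammaH2AX focus as a 3-D Gaussian spot centred on its plane and
    attenuated in adjacent planes, plus additive background noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from fociscreen.conditions import CONDITION_ORDER, GROUPS

RECORD_COLUMNS = ["individual_id", "group", "condition", "cell_index", "foci_count"]

#: Conditions whose rate each planted outlier class multiplies.
OUTLIER_CLASSES: dict[str, tuple[str, ...]] = {
    "preexisting_only": ("preexisting",),
    "both": ("preexisting", "remaining"),
    "remaining_only": ("remaining",),
}


@dataclass
class CohortParams:
    """Parameters of the synthetic cohort.

    The per-condition baseline means default to the study's reported group
    means for preexisting and remaining foci (0.49 / 2.63 foci per cell for
    healthy individuals, 0.59 / 2.97 for patients).  No mean is reported
    for the initial condition (0.5 Gy, 30 min); its default of 5.0 foci per
    cell is an uncalibrated placeholder with no group difference.

    Attributes
    ----------
    n_individuals:
        Group sizes, ``{"HI": ..., "RC": ...}``.
    means:
        Baseline mean foci/cell per group and condition.
    tau:
        Between-individual SD of the latent rate, per condition (foci/cell).
    phi:
        Within-individual overdispersion; cell counts are negative-binomial
        with variance ``lam * (1 + phi * lam)``.  ``phi = 0`` gives Poisson.
    outlier_fraction:
        Per-group probability that an individual is a planted outlier.
    outlier_effect:
        Multiplicative shift applied to the latent rate on the conditions
        the planted class affects.
    outlier_class_weights:
        Sampling weights over the three outlier classes; must sum to 1.
    cells_per_individual:
        Number of cells scored per individual and condition.
    rate_floor:
        Lower truncation of the latent rate (foci/cell).
    seed:
        Seed for the generator; identical params + seed give bit-identical
        tables.
    """

    n_individuals: dict[str, int] = field(
        default_factory=lambda: {"HI": 59, "RC": 136}
    )
    means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "HI": {"preexisting": 0.49, "initial": 5.0, "remaining": 2.63},
            "RC": {"preexisting": 0.59, "initial": 5.0, "remaining": 2.97},
        }
    )
    tau: dict[str, float] = field(
        default_factory=lambda: {"preexisting": 0.15, "initial": 1.0, "remaining": 0.60}
    )
    phi: float = 0.5
    outlier_fraction: dict[str, float] = field(
        default_factory=lambda: {"HI": 0.0, "RC": 0.12}
    )
    outlier_effect: float = 2.5
    outlier_class_weights: dict[str, float] = field(
        default_factory=lambda: {
            "preexisting_only": 1 / 3,
            "both": 1 / 3,
            "remaining_only": 1 / 3,
        }
    )
    cells_per_individual: int = 1000
    rate_floor: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for group in GROUPS:
            if self.n_individuals.get(group, 0) < 0:
                raise ValueError(f"negative group size for {group!r}")
            for cond in CONDITION_ORDER:
                mu = self.means[group][cond]
                if not mu > 0:
                    raise ValueError(
                        f"mean for {group}/{cond} must be positive, got {mu}"
                    )
            p = self.outlier_fraction.get(group, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"outlier_fraction for {group} not in [0, 1]: {p}")
        for cond, t in self.tau.items():
            if t < 0:
                raise ValueError(f"tau for {cond} must be >= 0, got {t}")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        if self.outlier_effect <= 0:
            raise ValueError("outlier_effect must be positive")
        w = sum(self.outlier_class_weights.get(c, 0.0) for c in OUTLIER_CLASSES)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"outlier class weights must sum to 1, got {w}")
        if self.cells_per_individual < 1:
            raise ValueError("cells_per_individual must be >= 1")
        if not self.rate_floor > 0:
            raise ValueError("rate_floor must be positive")

    def replace(self, **kwargs) -> "CohortParams":
        return dataclasses.replace(self, **kwargs)


def _truncated_normal_rate(mu: float, tau: float, floor: float, rng) -> float:
    """Draw one latent rate from Gaussian(mu, tau) truncated at ``floor``."""
    if tau == 0:
        return max(mu, floor)
    a = (floor - mu) / tau
    return float(stats.truncnorm.rvs(a, np.inf, loc=mu, scale=tau, random_state=rng))


def _draw_counts(lam: float, phi: float, size: int, rng) -> np.ndarray:
    """Cell counts with mean ``lam`` and variance ``lam * (1 + phi * lam)``."""
    if phi == 0:
        return rng.poisson(lam, size=size)
    r = 1.0 / phi
    p = r / (r + lam)
    return rng.negative_binomial(r, p, size=size)


def generate_cohort(params: CohortParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-cell foci-count records and the planted truth.

    Returns
    -------
    records:
        One row per scored cell with columns
        ``individual_id, group, condition, cell_index, foci_count``
        (``cell_index`` is the 1-based scoring position).
    truth:
        One row per individual and condition with the latent rate and the
        planted outlier class (``none`` for unaffected individuals).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    class_names = list(OUTLIER_CLASSES)
    class_w = np.array([params.outlier_class_weights[c] for c in class_names])

    ids: list[str] = []
    grps: list[str] = []
    conds: list[str] = []
    count_blocks: list[np.ndarray] = []
    truth_rows: list[dict] = []
    m = params.cells_per_individual
    for group in GROUPS:
        n = params.n_individuals.get(group, 0)
        p_out = params.outlier_fraction.get(group, 0.0)
        for i in range(n):
            ind_id = f"{group}-{i + 1:03d}"
            is_outlier = rng.random() < p_out
            out_class = (
                class_names[rng.choice(len(class_names), p=class_w)]
                if is_outlier
                else "none"
            )
            affected = OUTLIER_CLASSES.get(out_class, ())
            for cond in CONDITION_ORDER:
                lam = _truncated_normal_rate(
                    params.means[group][cond],
                    params.tau[cond],
                    params.rate_floor,
                    rng,
                )
                if cond in affected:
                    lam *= params.outlier_effect
                count_blocks.append(
                    _draw_counts(lam, params.phi, m, rng).astype(np.int64)
                )
                ids.append(ind_id)
                grps.append(group)
                conds.append(cond)
                truth_rows.append(
                    {
                        "individual_id": ind_id,
                        "group": group,
                        "condition": cond,
                        "true_rate": lam,
                        "outlier_class": out_class,
                    }
                )
    n_blocks = len(count_blocks)
    records = pd.DataFrame(
        {
            "individual_id": np.repeat(np.array(ids, dtype=object), m),
            "group": np.repeat(np.array(grps, dtype=object), m),
            "condition": np.repeat(np.array(conds, dtype=object), m),
            "cell_index": np.tile(np.arange(1, m + 1), n_blocks),
            "foci_count": (
                np.concatenate(count_blocks)
                if count_blocks
                else np.array([], dtype=np.int64)
            ),
        },
        columns=RECORD_COLUMNS,
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["individual_id", "group", "condition", "true_rate", "outlier_class"],
    )
    return records, truth


# ---------------------------------------------------------------------------
# Image truth and rendering
# ---------------------------------------------------------------------------


@dataclass
class NucleusTruth:
    """Ground truth for one nucleus in a synthetic field.

    ``foci`` is a list of ``(y, x, plane)`` positions inside the nucleus.
    Apoptotic nuclei carry ``fragments``: ``(y, x, radius)`` sub-disks that
    replace the single disk in the DAPI channel.
    """

    center: tuple[float, float]
    radius: float
    apoptotic: bool = False
    foci: list[tuple[float, float, int]] = field(default_factory=list)
    fragments: list[tuple[float, float, float]] = field(default_factory=list)


@dataclass
class ImageTruth:
    """Geometry, optics and noise of a synthetic two-channel field."""

    shape: tuple[int, int] = (512, 512)
    n_planes: int = 5
    plane_spacing_um: float = 0.75
    pixel_size_um: float = 0.2
    nuclei: list[NucleusTruth] = field(default_factory=list)
    background: float = 200.0
    noise_sd: float = 15.0
    nucleus_intensity: float = 3000.0
    focus_amplitude: float = 2000.0
    focus_sigma_px: float = 1.8
    focus_sigma_z_um: float = 0.9
    edge_softness_px: float = 1.5
    seed: int = 0

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "nucleus_id": i,
                "center_y": n.center[0],
                "center_x": n.center[1],
                "radius_px": n.radius,
                "apoptotic": n.apoptotic,
                "n_foci": len(n.foci),
            }
            for i, n in enumerate(self.nuclei)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "nucleus_id",
                "center_y",
                "center_x",
                "radius_px",
                "apoptotic",
                "n_foci",
            ],
        )


def generate_image_truth(
    n_nuclei: int = 50,
    mean_foci: float = 2.0,
    shape: tuple[int, int] = (512, 512),
    radius_px: tuple[float, float] = (14.0, 20.0),
    apoptotic_fraction: float = 0.0,
    min_edge_gap_px: float = 12.0,
    min_focus_separation_px: float = 8.0,
    seed: int = 0,
    **truth_kwargs,
) -> ImageTruth:
    """Place non-overlapping nuclei and plant Poisson-distributed foci.

    Nucleus radii correspond to 5-10 um lymphocyte-nucleus diameters at the
    default 0.2 um pixel size.  Foci positions are uniform inside 80% of
    the nucleus radius, each on a random optical plane, and are re-drawn
    until pairwise separation reaches ``min_focus_separation_px`` — two
    diffraction-limited spots closer than that are not resolvable as
    distinct foci by any counting scheme, including the assay's.
    Placement is by dart throwing; raises if the field cannot accommodate
    ``n_nuclei``.
    """
    rng = np.random.default_rng(seed)
    truth = ImageTruth(shape=shape, seed=seed, **truth_kwargs)
    h, w = shape
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < n_nuclei:
        attempts += 1
        if attempts > 200 * n_nuclei:
            raise RuntimeError(
                f"could not place {n_nuclei} nuclei in a {shape} field"
            )
        r = rng.uniform(*radius_px)
        margin = r + min_edge_gap_px
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        if all(
            np.hypot(y - py, x - px) > r + pr + min_edge_gap_px
            for py, px, pr in placed
        ):
            placed.append((y, x, r))

    n_apo = int(round(apoptotic_fraction * n_nuclei))
    apo_idx = set(rng.choice(n_nuclei, size=n_apo, replace=False).tolist())
    for i, (y, x, r) in enumerate(placed):
        nuc = NucleusTruth(center=(y, x), radius=r, apoptotic=i in apo_idx)
        if nuc.apoptotic:
            # 3-4 well-separated condensed-chromatin fragments on a ring
            n_frag = int(rng.integers(3, 5))
            for k in range(n_frag):
                ang = 2 * np.pi * (k + rng.uniform(-0.1, 0.1)) / n_frag
                d = rng.uniform(0.55, 0.7) * r
                fr = rng.uniform(0.22, 0.3) * r
                nuc.fragments.append((y + d * np.sin(ang), x + d * np.cos(ang), fr))
        else:
            for _ in range(rng.poisson(mean_foci)):
                for _try in range(100):
                    ang = rng.uniform(0, 2 * np.pi)
                    d = np.sqrt(rng.uniform()) * 0.8 * r
                    fy, fx = y + d * np.sin(ang), x + d * np.cos(ang)
                    if all(
                        np.hypot(fy - oy, fx - ox) >= min_focus_separation_px
                        for oy, ox, _ in nuc.foci
                    ):
                        break
                plane = int(rng.integers(0, truth.n_planes))
                nuc.foci.append((fy, fx, plane))
        truth.nuclei.append(nuc)
    return truth


def _render_disk(img: np.ndarray, cy: float, cx: float, r: float,
                 intensity: float, softness: float) -> None:
    """Add a soft-edged disk to ``img`` in place (local window only)."""
    h, w = img.shape
    pad = int(np.ceil(r + 4 * softness))
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(yy - cy, xx - cx)
    # logistic edge profile: ~intensity inside, ~0 outside, soft over ~softness px
    img[y0:y1, x0:x1] += intensity / (1.0 + np.exp((d - r) / softness))


def _render_spot(img: np.ndarray, cy: float, cx: float, sigma: float,
                 amplitude: float) -> None:
    """Add an isotropic 2-D Gaussian spot to ``img`` in place."""
    if amplitude <= 0:
        return
    h, w = img.shape
    pad = int(np.ceil(5 * sigma))
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
    )


def generate_zstack(truth: ImageTruth):
    """Render a two-channel z-stack from an :class:`ImageTruth`.

    Returns ``(stack, table)`` where ``stack`` is an
    :class:`~fociscreen.imaging.ZStack` (uint16 planes) and ``table`` is the
    per-nucleus truth table.  Identical truth (including its seed) renders
    identical pixels.  Raises ``ValueError`` if any focus lies outside the
    image bounds.
    """
    from fociscreen.imaging import ZStack  # local import to avoid a cycle

    h, w = truth.shape
    for nuc in truth.nuclei:
        for fy, fx, fp in nuc.foci:
            if not (0 <= fy < h and 0 <= fx < w and 0 <= fp < truth.n_planes):
                raise ValueError(f"focus ({fy:.1f}, {fx:.1f}, plane {fp}) out of bounds")

    rng = np.random.default_rng(truth.seed)
    dz = truth.plane_spacing_um
    sz = truth.focus_sigma_z_um
    mid = (truth.n_planes - 1) / 2
    dapi = np.zeros((truth.n_planes, h, w), dtype=np.float64)
    foci = np.zeros_like(dapi)
    for p in range(truth.n_planes):
        # nuclei span the whole stack with mild axial fall-off
        axial = 1.0 - 0.08 * abs(p - mid)
        for nuc in truth.nuclei:
            cy, cx = nuc.center
            if nuc.apoptotic:
                for fy, fx, fr in nuc.fragments:
                    _render_disk(dapi[p], fy, fx, fr,
                                 axial * truth.nucleus_intensity,
                                 truth.edge_softness_px)
            else:
                _render_disk(dapi[p], cy, cx, nuc.radius,
                             axial * truth.nucleus_intensity,
                             truth.edge_softness_px)
            for fy, fx, fp in nuc.foci:
                att = np.exp(-((p - fp) * dz) ** 2 / (2 * sz**2))
                _render_spot(foci[p], fy, fx, truth.focus_sigma_px,
                             att * truth.focus_amplitude)

    out = []
    for chan in (dapi, foci):
        chan = chan + truth.background
        chan = chan + rng.normal(0.0, truth.noise_sd, size=chan.shape)
        out.append(np.clip(np.round(chan), 0, 65535).astype(np.uint16))

    stack = ZStack(
        nucleus=out[0],
        foci=out[1],
        plane_spacing_um=truth.plane_spacing_um,
        pixel_size_um=truth.pixel_size_um,
    )
    return stack, truth.to_table()
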