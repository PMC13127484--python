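"""Synthetic ground-truth generators for every analysis stage.

Each generator emulates one of the study's data types with its planted
truth known by construction, so the full pipeline is testable offline:

* an ortholog family in which a designated subset of records carries an
  arginine-rich N-terminal extension, with the alignment implied by
  construction (extensions left-padded with gaps elsewhere);
* FRAP ROI traces following the acquisition protocol (10 pre-bleach,
  2 bleach, 188 post-bleach frames at 0.21 s), with shared mono-exponential
  acquisition photobleaching and additive Gaussian noise;
* two-channel nucleus images with DAPI-dense chromocenters and focal or
  dispersed marker signal;
* gel-lane line scans of nucleosome ladders (Gaussian bands over a smear);
* ChIP-qPCR Ct tables obtained by inverting the delta-Ct formula.

Determinism: every generator draws from ``numpy.random.default_rng`` seeded
with its ``seed`` argument; identical arguments give identical outputs.
:func:`derive_seed` yields independent per-stage substreams from one master
seed.
"""

from __future__ import annotations

import hashlib
import math

import numpy as np
import pandas as pd

from .errors import ParameterError
from .frap import FrapTrace, dual_exp
from .gel import LaneProfile
from .imaging import TwoChannelImage
from .survey import CANONICAL_AA, AlignedSet, ProteinRecord

# --------------------------------------------------------------------------
# Seeding
# --------------------------------------------------------------------------


def derive_seed(master_seed: int, label: str) -> int:
    """Independent substream seed for a named generator, < 2**31."""
    h = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# --------------------------------------------------------------------------
# Ortholog family
# --------------------------------------------------------------------------

# residue pools for planted extension classes (no ionizable side chains in
# the backgrounds, so planted basicity/acidity is unambiguous)
_SIMILAR_BG = "GSANQ"  # mouse-BD-like background
_DISTINCT_BG = "PTVLI"  # compositionally distinct background
_ACIDIC_BG = "DEGSA"  # pulls pI far below 10

REF_START_ACCESSION = "SYN-REF1"  # short paralog; extension start anchor
REF_BOUNDARY_ACCESSION = "SYN-REF2"  # long paralog; truncation anchor
REF_BOUNDARY_RESIDUE = 81


def _random_sequence(rng: np.random.Generator, length: int, pool: str) -> str:
    return "".join(rng.choice(list(pool), size=length))


def _extension(
    rng: np.random.Generator, length: int, arg_fraction: float, background: str
) -> str:
    n_arg = int(round(arg_fraction * length))
    seq = ["R"] * n_arg + list(_random_sequence(rng, length - n_arg, background))
    rng.shuffle(seq)
    return "".join(seq)


def gen_ortholog_family(
    n_total: int = 40,
    n_with_extension: int = 12,
    ext_length_range: tuple[int, int] = (5, 100),
    arg_fraction_range: tuple[float, float] = (0.2, 0.3),
    mutation_rate: float = 0.05,
    seed: int = 0,
    n_long: int | None = None,
    n_basic: int | None = None,
    n_similar: int | None = None,
    min_long_length: int = 20,
    core_length: int = 120,
    n_decoys: int = 0,
) -> tuple[list[ProteinRecord], AlignedSet, pd.DataFrame]:
    """Build an ortholog family with planted N-terminal extensions.

    A conserved core sequence receives i.i.d. point substitutions per
    record; ``n_with_extension`` records are prepended with extensions.
    Planted strata (all optional; sampled when None):

    * ``n_long`` extensions strictly longer than ``min_long_length``
      residues (the rest are short and fail the length filter);
    * ``n_basic`` of the long ones arginine-rich with a neutral background
      (pI far above 10 by construction); the remaining long ones
      aspartate/glutamate-rich (pI far below 10);
    * ``n_similar`` of the basic ones drawn on the reference-like
      background, the rest on a compositionally distinct background.

    Record ``SYN-REF1`` is the short reference (no extension; anchors the
    extension-start column) and ``SYN-REF2`` the long reference (exactly
    81-residue basic extension; anchors the truncation boundary).

    Returns (records, alignment, truth table).
    """
    if n_with_extension > n_total:
        raise ParameterError("n_with_extension > n_total")
    if n_with_extension < 0 or n_total < 2:
        raise ParameterError("need >= 2 records")
    rng = np.random.default_rng(seed)

    if n_with_extension == 0:
        n_long = n_basic = n_similar = 0
    elif n_long is None:
        n_long = sum(
            1
            for _ in range(n_with_extension - 1)
            if rng.integers(*ext_length_range, endpoint=True) > min_long_length
        ) + 1  # the 81-aa reference extension is always long
    if n_with_extension > 0:
        if not 1 <= n_long <= n_with_extension:
            raise ParameterError("n_long must be in [1, n_with_extension]")
        if n_basic is None:
            n_basic = n_long
        if not 1 <= n_basic <= n_long:
            raise ParameterError("n_basic must be in [1, n_long]")
        if n_similar is None:
            n_similar = max(1, (n_basic + 1) // 2)
        if not 1 <= n_similar <= n_basic:
            raise ParameterError("n_similar must be in [1, n_basic]")

    core = _random_sequence(rng, core_length, CANONICAL_AA)
    aa = np.array(list(CANONICAL_AA))

    # plan extensions: index 0 of the extension list is the long reference
    lo, hi = ext_length_range
    long_hi = max(hi, min_long_length + 2)
    lengths = [REF_BOUNDARY_RESIDUE] if n_with_extension else []
    lengths += [
        int(rng.integers(min_long_length + 1, long_hi, endpoint=True))
        for _ in range(n_long - 1)
    ]
    lengths += [
        int(rng.integers(max(2, lo), min_long_length, endpoint=True))
        for _ in range(n_with_extension - n_long)
    ]

    ext_seqs: list[str] = []
    ext_class: list[str] = []  # similar | distinct | acidic | short
    for j, length in enumerate(lengths):
        arg_frac = float(rng.uniform(*arg_fraction_range))
        if j >= n_long:
            ext_seqs.append(_extension(rng, length, arg_frac, _SIMILAR_BG))
            ext_class.append("short")
        elif j < n_similar:
            ext_seqs.append(_extension(rng, length, arg_frac, _SIMILAR_BG))
            ext_class.append("similar")
        elif j < n_basic:
            ext_seqs.append(_extension(rng, length, arg_frac, _DISTINCT_BG))
            ext_class.append("distinct")
        else:
            ext_seqs.append(_extension(rng, length, 0.02, _ACIDIC_BG))
            ext_class.append("acidic")

    max_ext = max(lengths, default=0)
    records, rows, truth = [], [], []
    for i in range(n_total):
        if i == 0:
            acc = REF_START_ACCESSION
        elif i == 1:
            acc = REF_BOUNDARY_ACCESSION
        else:
            acc = f"SYN{i:04d}"
        mutated = np.array(list(core))
        hit = rng.random(core_length) < mutation_rate
        mutated[hit] = aa[rng.integers(0, 20, size=int(hit.sum()))]
        core_i = "".join(mutated)

        # record 0 never gets an extension; records 1..n_with_extension do
        if 1 <= i <= n_with_extension:
            ext = ext_seqs[i - 1]
            cls = ext_class[i - 1]
        else:
            ext, cls = "", ""
        seq = ext + core_i
        name = f"Histone-lysine N-methyltransferase SUV39H-like protein {i}"
        org = f"Synthorganism species{i:03d}"
        records.append(ProteinRecord(acc, name, org, seq))
        rows.append((acc, "-" * (max_ext - len(ext)) + ext + core_i))
        truth.append(
            {
                "accession": acc,
                "protein_name": name,
                "organism": org,
                "has_extension": bool(ext),
                "ext_length": len(ext),
                "ext_sequence": ext,
                "is_long": len(ext) > min_long_length,
                "is_basic": cls in ("similar", "distinct"),
                "cluster_class": cls if cls in ("similar", "distinct") else "",
                "is_ref_start": acc == REF_START_ACCESSION,
                "is_ref_boundary": acc == REF_BOUNDARY_ACCESSION,
            }
        )

    for d in range(n_decoys):
        acc = f"DECOY{d:03d}"
        seq = _random_sequence(rng, core_length, CANONICAL_AA)
        name = (
            f"Histone PRDM-like zinc finger protein {d}"
            if d % 2 == 0
            else f"Histone SETMAR-like transposase fusion {d}"
        )
        records.append(ProteinRecord(acc, name, f"Decoyorganism {d}", seq))
        rows.append((acc, "-" * max_ext + seq))
        truth.append(
            {
                "accession": acc,
                "protein_name": name,
                "organism": f"Decoyorganism {d}",
                "has_extension": False,
                "ext_length": 0,
                "ext_sequence": "",
                "is_long": False,
                "is_basic": False,
                "cluster_class": "",
                "is_ref_start": False,
                "is_ref_boundary": False,
            }
        )

    return records, AlignedSet.from_rows(rows), pd.DataFrame(truth)


# --------------------------------------------------------------------------
# FRAP traces
# --------------------------------------------------------------------------


def solve_dual_exp_params(
    mobile_fraction: float, t_half: float, split: float = 0.7, tau_ratio: float = 2.0
) -> tuple[float, float, float, float]:
    """Map (mobile fraction, half-time) to dual-exponential parameters.

    Amplitudes are split ``split``/(1-split) between the fast and slow
    terms and tau2 = tau_ratio * tau1; tau1 is solved by bisection so that
    the recovery reaches half its plateau exactly at ``t_half``.
    """
    if not 0 < mobile_fraction <= 1:
        raise ParameterError("mobile_fraction must be in (0, 1]")
    if t_half <= 0:
        raise ParameterError("t_half must be > 0")

    def half_gap(tau1: float) -> float:
        return (
            split * (1.0 - math.exp(-t_half / tau1))
            + (1.0 - split) * (1.0 - math.exp(-t_half / (tau_ratio * tau1)))
            - 0.5
        )

    lo, hi = 1e-6, 1e6
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if half_gap(mid) > 0:
            lo = mid
        else:
            hi = mid
    tau1 = math.sqrt(lo * hi)
    return (
        split * mobile_fraction,
        tau1,
        (1.0 - split) * mobile_fraction,
        tau_ratio * tau1,
    )


def gen_frap_traces(
    mobile_fraction: float | None = None,
    t_half: float | None = None,
    params: tuple[float, float, float, float] | None = None,
    n_traces: int = 30,
    noise_sd: float = 0.05,
    acq_bleach_rate: float = 0.005,
    seed: int = 0,
    n_prebleach: int = 10,
    n_bleachframes: int = 2,
    n_postbleach: int = 188,
    frame_interval: float = 0.21,
    bleach_depth: float = 0.3,
    prebleach_level: float = 1000.0,
    reference_level: float = 800.0,
    background_level: float = 50.0,
) -> tuple[list[FrapTrace], dict]:
    """Simulate FRAP ROI traces with known recovery kinetics.

    Either ``params = (A1, tau1, A2, tau2)`` or ``(mobile_fraction,
    t_half)`` must be given; in the latter case parameters come from
    :func:`solve_dual_exp_params`.  Per trace: a pre-bleach plateau, a drop
    to ``bleach_depth`` of the plateau, and dual-exponential recovery
    scaled by the mobile fraction; bleach and reference ROIs share
    mono-exponential acquisition photobleaching at ``acq_bleach_rate``
    (1/s); background is constant; Gaussian noise with SD ``noise_sd`` x
    pre-bleach signal is added per frame.
    """
    if params is None:
        if mobile_fraction is None or t_half is None:
            raise ParameterError("give either params or (mobile_fraction, t_half)")
        if mobile_fraction == 0:
            params = (0.0, 1.0, 0.0, 8.0)
        else:
            params = solve_dual_exp_params(mobile_fraction, t_half)
    a1, tau1, a2, tau2 = params
    if a1 < 0 or a2 < 0 or a1 + a2 > 1 or tau1 <= 0 or tau2 <= 0:
        raise ParameterError("invalid dual-exponential parameters")
    if not 0 < bleach_depth < 1:
        raise ParameterError("bleach_depth must be in (0, 1)")

    rng = np.random.default_rng(seed)
    n_frames = n_prebleach + n_bleachframes + n_postbleach
    times = np.arange(n_frames) * frame_interval
    first_post = n_prebleach + n_bleachframes
    t_post = times[first_post:] - times[first_post]

    # noiseless normalized bleach-ROI signal relative to pre-bleach
    shape = np.ones(n_frames)
    # transition frames ramp down toward the bleach depth (discarded anyway)
    for j in range(n_bleachframes):
        shape[n_prebleach + j] = 1.0 - (1.0 - bleach_depth) * (j + 1) / (
            n_bleachframes + 1
        )
    recovery = dual_exp(t_post, a1, tau1, a2, tau2)
    shape[first_post:] = bleach_depth + (1.0 - bleach_depth) * recovery

    decay = np.exp(-acq_bleach_rate * times)
    sd = noise_sd * prebleach_level
    traces = []
    for _ in range(n_traces):
        bleach = background_level + prebleach_level * decay * shape
        ref = background_level + reference_level * decay
        bg = np.full(n_frames, background_level)
        if sd > 0:
            bleach = bleach + rng.normal(0.0, sd, n_frames)
            ref = ref + rng.normal(0.0, sd, n_frames)
            bg = bg + rng.normal(0.0, 0.1 * sd, n_frames)
        traces.append(
            FrapTrace(
                frame_times=times.copy(),
                bleach_roi=bleach,
                reference_roi=ref,
                background_roi=bg,
                n_prebleach=n_prebleach,
                n_bleachframes=n_bleachframes,
            )
        )

    plateau = a1 + a2
    if plateau > 0:
        if t_half is None:
            # half-time of the planted model, by bisection
            lo, hi = 0.0, 10.0 * tau2
            for _ in range(100):
                mid = 0.5 * (lo + hi)
                if dual_exp(np.array([mid]), a1, tau1, a2, tau2)[0] < plateau / 2:
                    lo = mid
                else:
                    hi = mid
            t_half_true = 0.5 * (lo + hi)
        else:
            t_half_true = t_half
    else:
        t_half_true = math.nan
    truth = {
        "A1": a1,
        "tau1": tau1,
        "A2": a2,
        "tau2": tau2,
        "mobile_pct": 100.0 * plateau,
        "t_half_s": t_half_true,
        "bleach_depth": bleach_depth,
        "noise_sd": noise_sd,
        "acq_bleach_rate": acq_bleach_rate,
        "seed": seed,
    }
    return traces, truth


# --------------------------------------------------------------------------
# Nucleus images
# --------------------------------------------------------------------------


def gen_nucleus_images(
    n_cells: int = 100,
    frac_focal: float = 0.7,
    foci_per_nucleus: tuple[int, int] = (2, 5),
    enrichment: float = 2.5,
    noise_sd: float = 0.05,
    seed: int = 0,
    image_size: int = 256,
    nuclei_per_image: int = 4,
    nucleus_radius: tuple[float, float] = (16.0, 24.0),
    nucleoplasm_level: float = 100.0,
    focus_sigma: float = 3.0,
    max_tries: int = 500,
) -> tuple[list[TwoChannelImage], pd.DataFrame]:
    """Simulate two-channel nucleus images with known focal/dispersed truth.

    Elliptical nuclei on a black background; the DAPI channel carries
    bright Gaussian chromocenters (amplitude 2x the nucleoplasm, i.e. 3x
    peak); the marker channel is co-enriched over the chromocenters by
    ``enrichment`` for the planted focal fraction of cells and uniform for
    the rest.  Gaussian noise with SD ``noise_sd`` x nucleoplasm level is
    added to both channels.
    """
    if not 0 <= frac_focal <= 1:
        raise ParameterError("frac_focal must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_focal = int(round(frac_focal * n_cells))
    is_focal = np.array([True] * n_focal + [False] * (n_cells - n_focal))
    rng.shuffle(is_focal)

    yy, xx = np.mgrid[0:image_size, 0:image_size]
    images, truth = [], []
    cell = 0
    img_idx = 0
    while cell < n_cells:
        n_here = min(nuclei_per_image, n_cells - cell)
        dapi = np.zeros((image_size, image_size))
        marker = np.zeros((image_size, image_size))
        placed: list[tuple[float, float, float]] = []
        for _ in range(n_here):
            for attempt in range(max_tries):
                a = rng.uniform(*nucleus_radius)
                b = rng.uniform(*nucleus_radius)
                margin = max(a, b) + 4
                cy = rng.uniform(margin, image_size - margin)
                cx = rng.uniform(margin, image_size - margin)
                if all(
                    (cy - py) ** 2 + (cx - px) ** 2 > (max(a, b) + pr + 12) ** 2
                    for py, px, pr in placed
                ):
                    break
            else:
                raise ParameterError("could not place non-overlapping nuclei")
            placed.append((cy, cx, max(a, b)))
            theta = rng.uniform(0, math.pi)
            dy, dx = yy - cy, xx - cx
            u = dy * math.cos(theta) + dx * math.sin(theta)
            v = -dy * math.sin(theta) + dx * math.cos(theta)
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0

            focal = bool(is_focal[cell])
            n_target = int(rng.integers(*foci_per_nucleus, endpoint=True))
            dapi_n = np.where(inside, nucleoplasm_level, 0.0)
            marker_base = 0.8 * nucleoplasm_level
            marker_n = np.where(inside, marker_base, 0.0)
            # non-overlapping focus centers so each planted focus stays a
            # distinct connected component for the detector
            centers: list[tuple[float, float]] = []
            min_sep = 5.0 * focus_sigma
            for _f in range(n_target):
                for _try in range(max_tries):
                    r = rng.uniform(0.0, 0.6)
                    phi = rng.uniform(0, 2 * math.pi)
                    fy = cy + r * a * math.sin(phi)
                    fx = cx + r * b * math.cos(phi)
                    if all(
                        (fy - py) ** 2 + (fx - px) ** 2 >= min_sep**2
                        for py, px in centers
                    ):
                        centers.append((fy, fx))
                        break
            n_foci = len(centers)
            for fy, fx in centers:
                d2 = (yy - fy) ** 2 + (xx - fx) ** 2
                blob = np.exp(-d2 / (2 * focus_sigma**2))
                dapi_n += 2.0 * nucleoplasm_level * blob * inside
            if focal and n_foci:
                # plant the marker enrichment on the DAPI-dense region as
                # defined by the same criterion the scorer applies (mean +
                # 2 SD within the nucleus, on the noiseless channel), so
                # the planted ratio is the measurable one
                vals = dapi_n[inside]
                focus_region = inside & (dapi_n > vals.mean() + 2.0 * vals.std())
                marker_n += (enrichment - 1.0) * marker_base * focus_region
            dapi += dapi_n
            marker += marker_n
            truth.append(
                {
                    "cell_index": cell,
                    "image_index": img_idx,
                    "center_y": cy,
                    "center_x": cx,
                    "n_foci": n_foci,
                    "true_class": "focal" if focal else "dispersed",
                }
            )
            cell += 1
        if noise_sd > 0:
            dapi = dapi + rng.normal(0, noise_sd * nucleoplasm_level, dapi.shape)
            marker = marker + rng.normal(0, noise_sd * nucleoplasm_level, marker.shape)
        images.append(
            TwoChannelImage(np.clip(dapi, 0, None), np.clip(marker, 0, None))
        )
        img_idx += 1
    return images, pd.DataFrame(truth)


# --------------------------------------------------------------------------
# Gel lane profiles
# --------------------------------------------------------------------------


def gen_lane_profile(
    n_nucleosome_bands: int = 5,
    spacing_px: float = 40.0,
    band_sd_px: float = 4.0,
    smear_amplitude: float = 20.0,
    seed: int = 0,
    length: int = 400,
    band_amplitude: float = 100.0,
    first_band_px: float = 60.0,
    noise_sd: float = 1.0,
    label: str = "",
) -> tuple[LaneProfile, dict]:
    """One gel-lane line scan: Gaussian bands at arithmetic positions over
    a broad smear, plus Gaussian noise (clipped at zero)."""
    if n_nucleosome_bands < 0:
        raise ParameterError("n_nucleosome_bands must be >= 0")
    rng = np.random.default_rng(seed)
    x = np.arange(length, dtype=float)
    centers = first_band_px + spacing_px * np.arange(n_nucleosome_bands)
    y = np.zeros(length)
    for c in centers:
        y += band_amplitude * np.exp(-((x - c) ** 2) / (2 * band_sd_px**2))
    if smear_amplitude > 0:
        y += smear_amplitude * np.exp(
            -((x - length / 2.0) ** 2) / (2 * (length / 4.0) ** 2)
        )
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, length)
    profile = LaneProfile(x, np.clip(y, 0, None), label)
    return profile, {"band_centers": centers, "seed": seed}


# --------------------------------------------------------------------------
# qPCR Ct tables
# --------------------------------------------------------------------------


def gen_ct_table(
    true_percent_input: dict[str, float],
    ct_sd: float = 0.2,
    n_replicates: int = 3,
    input_fraction: float = 0.01,
    seed: int = 0,
    target: str = "MSR",
    ct_input_base: float = 20.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant Ct values by inverting the delta-Ct formula, + Gaussian noise.

    For a sample with planted percent-of-input p:
    Ct_IP = Ct_input - log2(1 / input_fraction) - log2(p / 100).
    """
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for sample, pct in true_percent_input.items():
        if pct <= 0:
            raise ParameterError("percent_input must be > 0")
        for rep in range(1, n_replicates + 1):
            ct_in = ct_input_base + (rng.normal(0, ct_sd) if ct_sd > 0 else 0.0)
            ct_ip = (
                ct_in
                - math.log2(1.0 / input_fraction)
                - math.log2(pct / 100.0)
                + (rng.normal(0, ct_sd) if ct_sd > 0 else 0.0)
            )
            rows.append(
                {
                    "sample": sample,
                    "target": target,
                    "replicate": str(rep),
                    "Ct": ct_in,
                    "is_input": True,
                    "input_fraction": input_fraction,
                }
            )
            rows.append(
                {
                    "sample": sample,
                    "target": target,
                    "replicate": str(rep),
                    "Ct": ct_ip,
                    "is_input": False,
                    "input_fraction": np.nan,
                }
            )
        truth.append({"sample": sample, "true_percent_input": pct})
    return pd.DataFrame(rows), pd.DataFrame(truth)
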