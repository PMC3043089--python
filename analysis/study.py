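"""Shared study conditions for the numbered analysis scripts.

One synthetic cohort is used throughout: 50 class-I-like toy complexes
with docking angles uniform on [20, 110] degrees, coordinate noise 0.3 A,
and a planted binding-energy law BE = -22 + 0.12 * theta + N(0, 1)
kcal/mol.  A second, 12-complex cohort with 40% charge-flipped interfaces
drives the clustering study.  Both are fully determined by the seeds
below; every script regenerates them in memory.
"""

from pathlib import Path

from trpmhc.contacts import compute_contacts
from trpmhc.electrostatics import assign_formal_charges
from trpmhc.geometry import docking_angle, groove_plane, match_complementary_charges, peptide_axis
from trpmhc.structures import truncate_complex
from trpmhc.synth import generate_dataset

RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

MAIN_SEED = 2024
CLUSTER_SEED = 2025

MAIN_N = 50
THETA_RANGE = (20.0, 110.0)
BE_INTERCEPT = -22.0  # kcal/mol
BE_SLOPE = 0.12  # kcal/mol per degree
BE_NOISE_SD = 1.0  # kcal/mol
COORD_NOISE = 0.3  # Angstrom

CLUSTER_N = 12
FLIPPED_FRACTION = 0.4


def main_cohort():
    return generate_dataset(
        n=MAIN_N,
        theta_range=THETA_RANGE,
        a=BE_INTERCEPT,
        b=BE_SLOPE,
        noise_sd=BE_NOISE_SD,
        seed=MAIN_SEED,
        coordinate_noise=COORD_NOISE,
    )


def cluster_cohort():
    return generate_dataset(
        n=CLUSTER_N,
        seed=CLUSTER_SEED,
        flipped_fraction=FLIPPED_FRACTION,
        coordinate_noise=COORD_NOISE,
    )


def measure_theta(structure) -> float:
    """The full geometric pipeline for one complex, returning theta (deg)."""
    pmhc, tr = truncate_complex(structure)
    cm = compute_contacts(pmhc, tr, 5.0)
    plane = groove_plane(pmhc, tr)
    ring = match_complementary_charges(
        assign_formal_charges(pmhc), assign_formal_charges(tr), cm, plane
    )
    return docking_angle(ring, peptide_axis(pmhc), plane).theta
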