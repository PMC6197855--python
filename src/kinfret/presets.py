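"""Ready-made binding schemes and default acquisition settings.

The canonical FRET levels used throughout are {0, 0.2, 0.4, 0.7}: 0 is the
ligand-free state, 0.4 the partially bound (contact-only) state, 0.7 the
fully docked state, and 0.2 an alternative partially bound conformation that
appears only in the branched scheme.
"""

from __future__ import annotations

from .kinetic_models import ExperimentCondition, KineticScheme, Rate
from .synthetic_data import EmissionModel

CANONICAL_LEVELS = (0.0, 0.2, 0.4, 0.7)

#: Default mean trace length (s) before donor photobleaching at high
#: excitation power; the low-power value is ~103 s.
DEFAULT_BLEACH_MEAN_S = 70.0


def two_step_scheme(
    k_on: float = 5.0e5,
    k_off: float = 0.28,
    k_dock: float = 10.0,
    k_undock: float = 0.004,
    bleach_rate: float = 1.0 / DEFAULT_BLEACH_MEAN_S,
) -> KineticScheme:
    """Sequential two-step binding: U <-> P <-> F.

    ``k_on`` is second order (M^-1 s^-1); the remaining rates are s^-1.
    The default ``k_undock`` is small so that back-excursions from the
    docked state are rare (of order 10% of trajectories within a bleach-
    limited observation window); it is a configurable placeholder, not a
    measured value.
    """
    return KineticScheme(
        ["U", "P", "F"],
        [0.0, 0.4, 0.7],
        {
            ("U", "P"): Rate(k_on, order=2),
            ("P", "U"): Rate(k_off),
            ("P", "F"): Rate(k_dock),
            ("F", "P"): Rate(k_undock),
        },
        photobleach_rate=bleach_rate,
    )


def contact_only_scheme(
    k_on: float = 5.0e5,
    k_off: float = 0.28,
    bleach_rate: float = 1.0 / DEFAULT_BLEACH_MEAN_S,
) -> KineticScheme:
    """First binding step only (docking-incompetent ligand): U <-> P."""
    return KineticScheme(
        ["U", "P"],
        [0.0, 0.4],
        {("U", "P"): Rate(k_on, order=2), ("P", "U"): Rate(k_off)},
        photobleach_rate=bleach_rate,
    )


def branched_scheme(
    k_on: float = 5.4e4,
    k_unbind: float = 0.25,
    k_bend: float = 0.4,
    k_relax: float = 0.8,
    k_dock: float = 1.0,
    k_undock: float = 0.25,
    k_dock_direct: float = 0.08,
    k_undock_direct: float = 0.06,
    docking: bool = True,
    bleach_rate: float = 1.0 / DEFAULT_BLEACH_MEAN_S,
) -> KineticScheme:
    """Branched three-state binding: U <-> R <-> B <-> F with a direct R <-> F leak.

    R (FRET 0.2) and B (FRET 0.4) are two conformations of the partially
    bound state; F (FRET 0.7) is fully docked and can be reached either
    through B or directly from R.  ``docking=False`` removes both routes into
    F (docking-incompetent ligand).  Except for ``k_on``, the default
    magnitudes are chosen to be resolvable at a 100 ms frame time; they are
    configuration defaults, not measured values.
    """
    rates = {
        ("U", "R"): Rate(k_on, order=2),
        ("R", "U"): Rate(k_unbind),
        ("R", "B"): Rate(k_bend),
        ("B", "R"): Rate(k_relax),
    }
    if not docking:
        # docking-incompetent ligand: the docked state is dropped entirely
        return KineticScheme(
            ["U", "R", "B"], [0.0, 0.2, 0.4], rates, photobleach_rate=bleach_rate
        )
    rates[("B", "F")] = Rate(k_dock)
    rates[("F", "B")] = Rate(k_undock)
    rates[("R", "F")] = Rate(k_dock_direct)
    rates[("F", "R")] = Rate(k_undock_direct)
    return KineticScheme(
        ["U", "R", "B", "F"],
        [0.0, 0.2, 0.4, 0.7],
        rates,
        photobleach_rate=bleach_rate,
    )


def default_condition(
    ligand_concentration: float = 30e-9,
    frame_time: float = 0.1,
    acquisition_frames: int = 1500,
    injection_time: float | None = None,
) -> ExperimentCondition:
    """100 ms frames, 1500 frames, 30 nM ligand unless overridden."""
    return ExperimentCondition(
        ligand_concentration, frame_time, acquisition_frames, injection_time
    )


def default_emission(
    total_intensity: float = 1000.0,
    noise_sd: float = 50.0,
    bleedthrough_fraction: float = 0.1,
    baseline_donor: float = 0.0,
    baseline_acceptor: float = 0.0,
    donor_bleach_rate: float = 1.0 / DEFAULT_BLEACH_MEAN_S,
    acceptor_bleach_rate: float = 0.0,
) -> EmissionModel:
    """Invented rendering defaults; magnitudes are config-exposed.

    The acceptor bleach rate defaults to zero because the acceptor is
    carried by the ligand: every binding event brings a fresh fluorophore,
    so a single per-molecule acceptor bleach time does not apply.  Set a
    positive rate to emulate intramolecular labelling.
    """
    return EmissionModel(
        total_intensity=total_intensity,
        noise_sd=noise_sd,
        bleedthrough_fraction=bleedthrough_fraction,
        baseline_donor=baseline_donor,
        baseline_acceptor=baseline_acceptor,
        donor_bleach_rate=donor_bleach_rate,
        acceptor_bleach_rate=acceptor_bleach_rate,
    )
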