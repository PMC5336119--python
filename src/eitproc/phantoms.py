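"""Constructed test phantoms and protocols (synthetic stand-ins).

Everything here is synthetic and deterministic: transfer-impedance tables
and protocols *constructed* to mirror the measurement-count structure of
bench characterisation set-ups — a 34-pair/16-electrode resistor-box
phantom whose 544 single-ended measurements reduce to exactly 363 after
rejecting injection electrodes and boundary voltages below 250 uV at
100 uA, and a 31-pair/32-electrode scalp-like table whose 930 non-injection
measurements reduce to exactly 540 above 1 mV at 160 uA. They are data
fixtures for regression tests and demonstrations, not measurements of any
physical device.
"""

from __future__ import annotations

import numpy as np

from .protocol import InjectionProtocol
from .simulator import DispersionModel, PhantomModel

__all__ = [
    "head_protocol_34_16",
    "scalp_protocol_31_32",
    "cardiff_like_phantom",
    "scalp_like_phantom",
    "reciprocal_phantom",
    "transfer_from_forward_model",
    "phantoms_from_forward_models",
]

_FIXTURE_SEED = 714  # fixed: these are constructed fixtures, not simulations


def _distinct_pairs(n_pairs: int, n_electrodes: int, rng: np.random.Generator):
    all_pairs = [
        (i, j) for i in range(1, n_electrodes + 1) for j in range(i + 1, n_electrodes + 1)
    ]
    idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
    return tuple(all_pairs[i] for i in sorted(idx))


def head_protocol_34_16(current_amplitude_a: float = 100e-6) -> InjectionProtocol:
    """Constructed 34-pair protocol on 16 electrodes (synthetic stand-in for
    a head-optimised pair selection)."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    return InjectionProtocol(
        _distinct_pairs(34, 16, rng), 16, current_amplitude_a, "head-34x16-synthetic"
    )


def scalp_protocol_31_32(current_amplitude_a: float = 160e-6) -> InjectionProtocol:
    """Constructed 31-pair protocol on 32 electrodes (synthetic)."""
    rng = np.random.default_rng(_FIXTURE_SEED + 1)
    return InjectionProtocol(
        _distinct_pairs(31, 32, rng), 32, current_amplitude_a, "scalp-31x32-synthetic"
    )


def _counted_table(
    protocol: InjectionProtocol,
    n_retained: int,
    current_a: float,
    retained_mean_v: float,
    retained_sd_v: float,
    low_range_v: tuple[float, float],
    injection_v: float,
    seed: int,
) -> np.ndarray:
    """Transfer table whose non-injection channels split into exactly
    ``n_retained`` with amplitudes around ``retained_mean_v`` and the rest
    inside ``low_range_v`` (below any sensible rejection threshold)."""
    rng = np.random.default_rng(seed)
    n_pairs, n_e = protocol.n_pairs, protocol.n_electrodes
    inj = protocol.injection_mask()
    n_non_inj = int((~inj).sum())
    if not 0 <= n_retained <= n_non_inj:
        raise ValueError("retained count exceeds available channels")

    amps = np.empty(n_non_inj)
    amps[:n_retained] = np.clip(
        rng.normal(retained_mean_v, retained_sd_v, n_retained),
        retained_mean_v - 3 * retained_sd_v,
        retained_mean_v + 3 * retained_sd_v,
    )
    amps[n_retained:] = rng.uniform(*low_range_v, n_non_inj - n_retained)
    rng.shuffle(amps)

    table = np.full((n_pairs, n_e), injection_v / current_a)
    table[~inj] = amps / current_a
    return table


def cardiff_like_phantom(
    protocol: InjectionProtocol | None = None,
    dispersion: DispersionModel | None = None,
    amplifier=None,
    carrier_hz: float = 2000.0,
) -> tuple[InjectionProtocol, PhantomModel]:
    """Resistor-box-like phantom: 544 measurements, exactly 363 retained
    after injection-electrode exclusion and a 250 uV threshold at 100 uA;
    retained amplitudes ~2.66 mV +/- 0.24 mV.

    Amplitudes are *recorded* values: when an amplifier model is given the
    table is pre-compensated for its anti-aliasing gain at ``carrier_hz``.
    """
    protocol = protocol or head_protocol_34_16()
    table = _counted_table(
        protocol,
        n_retained=363,
        current_a=protocol.current_amplitude_a,
        retained_mean_v=2.66e-3,
        retained_sd_v=0.24e-3,
        low_range_v=(60e-6, 220e-6),
        injection_v=15e-3,
        seed=_FIXTURE_SEED + 2,
    )
    if amplifier is not None:
        from .simulator import gain_filter

        table = table / gain_filter(amplifier, carrier_hz)
    return protocol, PhantomModel(protocol.n_electrodes, table, dispersion)


def scalp_like_phantom(
    protocol: InjectionProtocol | None = None,
    dispersion: DispersionModel | None = None,
    amplifier=None,
    carrier_hz: float = 1200.0,
) -> tuple[InjectionProtocol, PhantomModel]:
    """Scalp-like phantom: 930 non-injection measurements, exactly 540
    retained above 1 mV at 160 uA (recorded amplitudes; see
    :func:`cardiff_like_phantom` for the amplifier compensation)."""
    protocol = protocol or scalp_protocol_31_32()
    table = _counted_table(
        protocol,
        n_retained=540,
        current_a=protocol.current_amplitude_a,
        retained_mean_v=5.4e-3,
        retained_sd_v=1.0e-3,
        low_range_v=(0.15e-3, 0.8e-3),
        injection_v=25e-3,
        seed=_FIXTURE_SEED + 3,
    )
    if amplifier is not None:
        from .simulator import gain_filter

        table = table / gain_filter(amplifier, carrier_hz)
    return protocol, PhantomModel(protocol.n_electrodes, table, dispersion)


def reciprocal_phantom(
    protocol: InjectionProtocol,
    seed: int = 0,
    scale_ohm: float = 30.0,
    dispersion: DispersionModel | None = None,
) -> PhantomModel:
    """Exactly reciprocal phantom from a random symmetric positive
    transfer-resistance matrix (synthetic)."""
    rng = np.random.default_rng(seed)
    n = protocol.n_electrodes
    A = rng.uniform(0.2, 1.0, (n, n)) * scale_ohm
    R = (A + A.T) / 2
    return PhantomModel.from_resistance_matrix(R, protocol, dispersion)


def transfer_from_forward_model(forward_model, current_a: float = 1.0) -> np.ndarray:
    """Signed electrode voltages per injection pair (pairs, electrodes) for a
    unit (or given) current, mean-zero referenced."""
    return forward_model.boundary_voltages(current_a)


def phantoms_from_forward_models(
    fm_reference, fm_perturbed, margin: float = 0.1,
    dispersion: DispersionModel | None = None,
) -> tuple[PhantomModel, PhantomModel]:
    """Reference/perturbed phantom pair sharing a common per-pair offset.

    Both signed voltage tables (per unit current) are shifted by the *same*
    per-pair constant so all single-ended magnitudes are positive — the
    amplifier reference is stable between the two states, so differences of
    demodulated amplitudes equal differences of the signed voltages.
    """
    v_ref = transfer_from_forward_model(fm_reference)
    v_pert = transfer_from_forward_model(fm_perturbed)
    lo = np.minimum(v_ref.min(axis=1), v_pert.min(axis=1))
    hi = np.maximum(v_ref.max(axis=1), v_pert.max(axis=1))
    offset = -lo + margin * np.where(hi > lo, hi - lo, 1.0)
    n_e = v_ref.shape[1]
    mk = lambda v: PhantomModel(n_e, v + offset[:, None], dispersion)
    return mk(v_ref), mk(v_pert)
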