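"""Vectorised evaluation of the bicarbonate turnover model.

The turnover equation

    dB/dt = kin * (1 + F(t)/(F(t) + fur50))
            - kout * (1 + emax * A(t)/(A(t) + a50)) * B(t)

is linear in B with piecewise-exponential forcing (A and F are bolus
superpositions), so between dose times it admits the exact
integrating-factor solution

    B(t0 + tau) = exp(-beta(tau)) * (B(t0) + I(tau)),
    beta(tau)  = int_0^tau b(s) ds            (closed form),
    I(tau)     = int_0^tau a(s) exp(beta(s)) ds  (Gauss-Legendre).

With segments capped at MAX_SEGMENT days the quadrature is accurate to
machine precision for any physiologically plausible kout, which makes
this the primary integrator: it is exact at dose discontinuities and
vectorises over thousands of (subject, replicate) rows at once.
"""

from __future__ import annotations

import numpy as np

from .kinetics import LN2

# Gauss-Legendre rule on [0, 1]; 16 nodes keeps the within-segment
# quadrature error below ~1e-15 for segment lengths <= MAX_SEGMENT.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(16)
_GL_X = (_GL_X + 1.0) / 2.0
_GL_W = _GL_W / 2.0

MAX_SEGMENT = 0.25  # day


def _beta(tau, ca, kout, emax, a50, ka):
    """Integral of the elimination coefficient over [0, tau]."""
    # int_0^tau A/(A+a50) ds = (1/ka) * log((ca + a50)/(ca*exp(-ka*tau) + a50))
    drug = np.log((ca + a50) / (ca * np.exp(-ka * tau) + a50)) / ka
    return kout * (tau + emax * drug)


def _formation(s, cf, kin, fur50, kf):
    f = cf * np.exp(-kf * s)
    return kin * (1.0 + f / (f + fur50))


def bicar_step(b0, tau, ca, cf, kout, kin, emax, a50, fur50, ka, kf):
    """Advance the turnover solution by ``tau`` days (broadcastable arrays)."""
    b0, tau, ca, cf, kout, kin = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (b0, tau, ca, cf, kout, kin))
    )
    beta_tau = _beta(tau, ca, kout, emax, a50, ka)
    s = tau[..., None] * _GL_X
    # integrand shifted by beta(tau) so the exponent is always <= 0:
    # B(tau) = b0*exp(-beta(tau)) + int a(s) exp(beta(s)-beta(tau)) ds
    integrand = _formation(s, cf[..., None], kin[..., None], fur50, kf) * np.exp(
        _beta(s, ca[..., None], kout[..., None], emax, a50, ka) - beta_tau[..., None]
    )
    integral = tau * (integrand @ _GL_W)
    out = b0 * np.exp(-beta_tau) + integral
    # Stiff limit: when beta(tau) is large the memory of b0 is gone and
    # the quadrature under-resolves the boundary layer; the solution is
    # then quasi-static, B = a(tau)/b(tau), with relative error O(k/b).
    stiff = beta_tau > 15.0
    if np.any(stiff):
        a_end = _formation(tau, cf, kin, fur50, kf)
        a_drug = ca * np.exp(-ka * tau)
        b_end = kout * (1.0 + emax * a_drug / (a_drug + a50))
        out = np.where(stiff, a_end / b_end, out)
    return out


def build_boundaries(dose_times, t_max, max_segment=MAX_SEGMENT):
    """Segment boundaries: 0, all dose times, t_max, refined to ``max_segment``."""
    pts = np.unique(np.concatenate([[0.0], np.asarray(dose_times, float), [float(t_max)]]))
    pts = pts[(pts >= 0) & (pts <= t_max + 1e-12)]
    out = [pts[0]]
    for right in pts[1:]:
        left = out[-1]
        n_sub = max(1, int(np.ceil((right - left) / max_segment - 1e-12)))
        out.extend(left + (right - left) * np.arange(1, n_sub + 1) / n_sub)
    return np.asarray(out)


class BatchTrajectory:
    """Bicarbonate solution for ``n`` rows sharing one boundary grid.

    Parameters
    ----------
    boundaries : (S+1,) increasing from 0; every dose time of every row
        must be a boundary.
    ca, cf : (n, S+1) post-dose acetazolamide / furosemide amounts at
        each boundary (mg).
    bicar0, kout : (n,) individual baseline and turnover rate; the
        formation rate is ``kin = kout * bicar0`` (equilibrium start).
    """

    def __init__(self, boundaries, ca, cf, bicar0, kout, *, emax, a50, fur50,
                 half_life, fur_half_life):
        self.boundaries = np.asarray(boundaries, dtype=float)
        self.ca = np.atleast_2d(np.asarray(ca, dtype=float))
        self.cf = np.atleast_2d(np.asarray(cf, dtype=float))
        self.bicar0 = np.atleast_1d(np.asarray(bicar0, dtype=float))
        self.kout = np.atleast_1d(np.asarray(kout, dtype=float))
        self.kin = self.kout * self.bicar0
        self.emax = float(emax)
        self.a50 = float(a50)
        self.fur50 = float(fur50)
        self.ka = LN2 / float(half_life)
        self.kf = LN2 / float(fur_half_life)
        n, s1 = self.ca.shape
        if s1 != self.boundaries.size:
            raise ValueError("ca must have one column per boundary")
        # March the solution across segments.
        b = np.empty((n, s1))
        b[:, 0] = self.bicar0
        taus = np.diff(self.boundaries)
        for s, tau in enumerate(taus):
            b[:, s + 1] = bicar_step(
                b[:, s], tau, self.ca[:, s], self.cf[:, s],
                self.kout, self.kin, self.emax, self.a50, self.fur50,
                self.ka, self.kf,
            )
        self.b_bound = b

    def at(self, row_idx, times):
        """Bicarbonate for rows ``row_idx`` at ``times`` (flat arrays)."""
        times = np.asarray(times, dtype=float)
        row_idx = np.asarray(row_idx, dtype=int)
        seg = np.clip(np.searchsorted(self.boundaries, times, side="right") - 1,
                      0, self.boundaries.size - 1)
        tau = times - self.boundaries[seg]
        return bicar_step(
            self.b_bound[row_idx, seg], tau,
            self.ca[row_idx, seg], self.cf[row_idx, seg],
            self.kout[row_idx], self.kin[row_idx],
            self.emax, self.a50, self.fur50, self.ka, self.kf,
        )


def predict_observations(traj: BatchTrajectory, row_idx, times, dvid,
                         mv0, paco2_0, pow_mv_paco2, mv_mult, *,
                         pow_bicar_mv, bicar_ref):
    """Model predictions for a flat observation list.

    ``dvid`` codes: 0 = bicarbonate, 1 = minute ventilation, 2 = PaCO2.
    ``mv_mult`` is the per-row product of the ventilator-mode and sex
    multipliers. The PaCO2 link uses the subject's model MV baseline,
    under which the multipliers cancel:
    PaCO2 = paco2_0 * (B(t)/bicar0)**(pow_bicar_mv * pow_mv_paco2).
    """
    row_idx = np.asarray(row_idx, dtype=int)
    dvid = np.asarray(dvid, dtype=int)
    b = traj.at(row_idx, times)
    pred = np.empty_like(b)
    m = dvid == 0
    pred[m] = b[m]
    m = dvid == 1
    if np.any(m):
        r = row_idx[m]
        pred[m] = mv0[r] * mv_mult[r] * (bicar_ref / b[m]) ** pow_bicar_mv
    m = dvid == 2
    if np.any(m):
        r = row_idx[m]
        pred[m] = paco2_0[r] * (b[m] / traj.bicar0[r]) ** (
            pow_bicar_mv * pow_mv_paco2[r]
        )
    return pred
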