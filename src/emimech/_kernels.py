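"""Numba kernels: constitutive evaluation and mixed-system assembly.

The residual of the mixed weak form
    int_Omega P : grad(v) + q (J - 1) dX = 0
is assembled over quadratic displacement / linear pressure (Taylor–Hood)
tetrahedra.  The consistent tangent dP/dF is obtained by complex-step
differentiation of the analytic first Piola–Kirchhoff stress, which is
exact to machine precision (no finite-difference truncation), so Newton
retains quadratic convergence down to tight tolerances.
"""

import cmath

import numpy as np
from numba import njit

_CSTEP = 1e-30


@njit(cache=True)
def piola_cplx(F, g, p, a, b, af, bf, kappa, P):
    """First Piola–Kirchhoff stress (complex-capable) into ``P``.

    Augmented energy psi(I1, I4f) + p (J - 1) + kappa/2 (J - 1)^2 with the
    active-strain elastic factor F_p = F F_a^{-1}; fiber = first axis of
    the frame.  ``af = 0`` disables the fiber term (extracellular matrix);
    ``kappa`` is the augmented-Lagrangian stabilization modulus (kPa) that
    penalizes pointwise volume changes invisible to the weak constraint.
    """
    om = 1.0 - g
    w0 = 1.0 / (om * om)      # (F_a^{-1})_ff^2
    w1 = om                   # (F_a^{-1})_ss^2 = (F_a^{-1})_nn^2

    J = (F[0, 0] * (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1])
         - F[0, 1] * (F[1, 0] * F[2, 2] - F[1, 2] * F[2, 0])
         + F[0, 2] * (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0]))
    Jm23 = cmath.exp((-2.0 / 3.0) * cmath.log(J))

    c0 = F[0, 0] * F[0, 0] + F[1, 0] * F[1, 0] + F[2, 0] * F[2, 0]
    c1 = F[0, 1] * F[0, 1] + F[1, 1] * F[1, 1] + F[2, 1] * F[2, 1]
    c2 = F[0, 2] * F[0, 2] + F[1, 2] * F[1, 2] + F[2, 2] * F[2, 2]
    I1 = Jm23 * (w0 * c0 + w1 * (c1 + c2))
    I4 = Jm23 * w0 * c0

    # cofactor matrix, cof = J F^{-T}
    g00 = F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1]
    g01 = F[1, 2] * F[2, 0] - F[1, 0] * F[2, 2]
    g02 = F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0]
    g10 = F[0, 2] * F[2, 1] - F[0, 1] * F[2, 2]
    g11 = F[0, 0] * F[2, 2] - F[0, 2] * F[2, 0]
    g12 = F[0, 1] * F[2, 0] - F[0, 0] * F[2, 1]
    g20 = F[0, 1] * F[1, 2] - F[0, 2] * F[1, 1]
    g21 = F[0, 2] * F[1, 0] - F[0, 0] * F[1, 2]
    g22 = F[0, 0] * F[1, 1] - F[0, 1] * F[1, 0]

    dpsi1 = 0.5 * a * cmath.exp(b * (I1 - 3.0))
    q = I4 - 1.0
    use_fiber = (af != 0.0) and (q.real > 0.0)
    dpsi4 = af * q * cmath.exp(bf * q * q) if use_fiber else 0.0 + 0.0j

    f1 = -(2.0 / 3.0) * (dpsi1 * I1 + dpsi4 * I4) / J + p \
        + kappa * (J - 1.0)
    t1 = 2.0 * Jm23 * dpsi1
    t4 = 2.0 * Jm23 * dpsi4

    P[0, 0] = t1 * w0 * F[0, 0] + t4 * w0 * F[0, 0] + f1 * g00
    P[1, 0] = t1 * w0 * F[1, 0] + t4 * w0 * F[1, 0] + f1 * g01
    P[2, 0] = t1 * w0 * F[2, 0] + t4 * w0 * F[2, 0] + f1 * g02
    P[0, 1] = t1 * w1 * F[0, 1] + f1 * g10
    P[1, 1] = t1 * w1 * F[1, 1] + f1 * g11
    P[2, 1] = t1 * w1 * F[2, 1] + f1 * g12
    P[0, 2] = t1 * w1 * F[0, 2] + f1 * g20
    P[1, 2] = t1 * w1 * F[1, 2] + f1 * g21
    P[2, 2] = t1 * w1 * F[2, 2] + f1 * g22
    return J.real


@njit(cache=True)
def _cofactor(F, C):
    C[0, 0] = F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1]
    C[0, 1] = F[1, 2] * F[2, 0] - F[1, 0] * F[2, 2]
    C[0, 2] = F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0]
    C[1, 0] = F[0, 2] * F[2, 1] - F[0, 1] * F[2, 2]
    C[1, 1] = F[0, 0] * F[2, 2] - F[0, 2] * F[2, 0]
    C[1, 2] = F[0, 1] * F[2, 0] - F[0, 0] * F[2, 1]
    C[2, 0] = F[0, 1] * F[1, 2] - F[0, 2] * F[1, 1]
    C[2, 1] = F[0, 2] * F[1, 0] - F[0, 0] * F[1, 2]
    C[2, 2] = F[0, 0] * F[1, 1] - F[0, 1] * F[1, 0]


@njit(cache=True)
def assemble_system(conn10, connp, grads, detJ, qw, G2ref, N1,
                    u, pvals, gamma_el, intra_el, prm, kappa, need_K):
    """Assemble residual (and element tangents) of the mixed weak form.

    Parameters
    ----------
    conn10 : (nt, 10) P2 connectivity
    connp : (nt, 4) P1 (vertex) connectivity
    grads : (nt, nq, 10, 3) physical P2 shape gradients
    detJ : (nt,) affine Jacobian determinants (> 0)
    qw : (nq,) reference weights (sum to 1/6)
    G2ref, N1 : reference P2 gradients (unused here) and P1 values (nq, 4)
    u : (n2, 3) displacement dofs; pvals : (nv,) pressure dofs
    gamma_el : (nt,) activation per element; intra_el : (nt,) bool
    prm : (6,) a_i, b_i, a_if, b_if, a_e, b_e
    need_K : assemble element 34x34 tangents as well

    Returns (Ru, Rp, Kel, max|J-1|, ok_flag).
    """
    nt = conn10.shape[0]
    nq = qw.shape[0]
    n2 = u.shape[0]
    nv = pvals.shape[0]
    Ru = np.zeros((n2, 3))
    Rp = np.zeros(nv)
    if need_K:
        Kel = np.zeros((nt, 34, 34))
    else:
        Kel = np.zeros((1, 34, 34))
    Fc = np.zeros((3, 3), dtype=np.complex128)
    Pc = np.zeros((3, 3), dtype=np.complex128)
    Pr = np.zeros((3, 3))
    Fr = np.zeros((3, 3))
    cof = np.zeros((3, 3))
    A4 = np.zeros((3, 3, 3, 3))
    S = np.zeros((10, 3, 3, 3))   # S[b,k,i,j] = sum_l A[i,j,k,l] G[b,l]
    maxdev = 0.0
    ok = True

    for e in range(nt):
        gam = gamma_el[e]
        if intra_el[e]:
            a, b, af, bf = prm[0], prm[1], prm[2], prm[3]
        else:
            a, b, af, bf = prm[4], prm[5], 0.0, 0.0
        for iq in range(nq):
            wdet = qw[iq] * detJ[e]
            G = grads[e, iq]
            # deformation gradient F = I + sum_a u_a (x) G_a
            for i in range(3):
                for j in range(3):
                    s = 0.0
                    for n in range(10):
                        s += u[conn10[e, n], i] * G[n, j]
                    Fc[i, j] = s
                Fc[i, i] = Fc[i, i] + 1.0
            # pressure at qp
            pq = 0.0
            for c in range(4):
                pq += N1[iq, c] * pvals[connp[e, c]]

            Jr = piola_cplx(Fc, gam, pq, a, b, af, bf, kappa, Pc)
            if Jr <= 0.0:
                ok = False
                return Ru, Rp, Kel, maxdev, ok
            dev = abs(Jr - 1.0)
            if dev > maxdev:
                maxdev = dev
            for i in range(3):
                for j in range(3):
                    Pr[i, j] = Pc[i, j].real
                    Fr[i, j] = Fc[i, j].real
            _cofactor(Fr, cof)

            # residual
            for n in range(10):
                gn = conn10[e, n]
                for i in range(3):
                    s = 0.0
                    for j in range(3):
                        s += Pr[i, j] * G[n, j]
                    Ru[gn, i] += wdet * s
            for c in range(4):
                Rp[connp[e, c]] += wdet * N1[iq, c] * (Jr - 1.0)

            if not need_K:
                continue

            # consistent tangent via complex step on the analytic stress
            for k in range(3):
                for l in range(3):
                    Fc[k, l] = Fc[k, l] + 1j * _CSTEP
                    piola_cplx(Fc, gam, pq, a, b, af, bf, kappa, Pc)
                    Fc[k, l] = Fc[k, l] - 1j * _CSTEP
                    for i in range(3):
                        for j in range(3):
                            A4[i, j, k, l] = Pc[i, j].imag / _CSTEP

            for nb in range(10):
                for k in range(3):
                    for i in range(3):
                        for j in range(3):
                            s = 0.0
                            for l in range(3):
                                s += A4[i, j, k, l] * G[nb, l]
                            S[nb, k, i, j] = s
            Ke = Kel[e]
            for na in range(10):
                for nb in range(10):
                    for i in range(3):
                        for k in range(3):
                            s = 0.0
                            for j in range(3):
                                s += G[na, j] * S[nb, k, i, j]
                            Ke[3 * na + i, 3 * nb + k] += wdet * s
            # coupling: dP/dp = cof(F) = J F^{-T}; d(J-1)/dF likewise
            for na in range(10):
                for i in range(3):
                    s = 0.0
                    for j in range(3):
                        s += cof[i, j] * G[na, j]
                    for c in range(4):
                        v = wdet * s * N1[iq, c]
                        Ke[3 * na + i, 30 + c] += v
                        Ke[30 + c, 3 * na + i] += v
    return Ru, Rp, Kel, maxdev, ok


@njit(cache=True)
def subdomain_integrals(conn10, connp, grads, detJ, qw, N1, u, pvals,
                        gamma_el, intra_el, prm, kappa, el_mask, e0,
                        want_sigma):
    """Integrals of e0.(T e0) and volume over the masked elements.

    T is the Cauchy stress (want_sigma) or the Green–Lagrange strain.
    Returns (integral, volume).
    """
    nt = conn10.shape[0]
    nq = qw.shape[0]
    Fc = np.zeros((3, 3), dtype=np.complex128)
    Pc = np.zeros((3, 3), dtype=np.complex128)
    total = 0.0
    vol = 0.0
    for e in range(nt):
        if not el_mask[e]:
            continue
        gam = gamma_el[e]
        if intra_el[e]:
            a, b, af, bf = prm[0], prm[1], prm[2], prm[3]
        else:
            a, b, af, bf = prm[4], prm[5], 0.0, 0.0
        for iq in range(nq):
            wdet = qw[iq] * detJ[e]
            G = grads[e, iq]
            for i in range(3):
                for j in range(3):
                    s = 0.0
                    for n in range(10):
                        s += u[conn10[e, n], i] * G[n, j]
                    Fc[i, j] = s
                Fc[i, i] = Fc[i, i] + 1.0
            if want_sigma:
                pq = 0.0
                for c in range(4):
                    pq += N1[iq, c] * pvals[connp[e, c]]
                Jr = piola_cplx(Fc, gam, pq, a, b, af, bf, kappa, Pc)
                # sigma e0 . e0 = (P F^T e0).e0 / J
                s = 0.0
                for i in range(3):
                    for j in range(3):
                        for k in range(3):
                            s += e0[i] * Pc[i, k].real * Fc[j, k].real * e0[j]
                total += wdet * s / Jr
            else:
                # E = (F^T F - I)/2
                s = 0.0
                for i in range(3):
                    for j in range(3):
                        for k in range(3):
                            s += e0[i] * Fc[k, i].real * Fc[k, j].real * e0[j]
                s = 0.5 * (s - 1.0)
                total += wdet * s
            vol += wdet
    return total, vol
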