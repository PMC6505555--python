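"""Symbolic re-derivation of the moment hierarchy used by the 3MA/DM kernels.

Maintenance tool: regenerates, with sympy, the exact raw-moment equations of
the (gene, protein) pair for the bursty feedback loop up to order three, and
the zero-fourth-cumulant closure expressions, in the exact form hardcoded in
``mominf._kernels`` (state order M10, M01, M20, M11, M02, M30, M21, M12,
M03).  Run it after any change to the reaction scheme and diff the output
against the kernel source.

    python scripts/derive_moment_equations.py
"""

import sympy as sp
from sympy import Poly, expand, symbols

y, n, m = symbols("y n m")
r, sb, su, d = symbols("r sb su d")
e1, e2, e3 = symbols("e1 e2 e3")  # raw moments of the geometric burst law

TRACKED = [(1, 0), (0, 1), (2, 0), (1, 1), (0, 2), (3, 0), (2, 1), (1, 2), (0, 3)]
NAMES = {(0, 0): sp.Integer(1)}
for i, j in TRACKED:
    NAMES[(i, j)] = sp.Symbol(f"M{i}{j}")
for i, j in [(4, 0), (3, 1), (2, 2), (1, 3), (0, 4)]:
    NAMES[(i, j)] = sp.Symbol(f"Q{i}{j}")


def average(expr):
    """Replace monomials y^i n^j by moment symbols <y^i n^j>."""
    out = 0
    for (i, j), c in Poly(expand(expr), y, n).terms():
        out += c * NAMES[(i, j)]
    return out


def burst_average(expr):
    """Average over the burst size m using E[m^k] = e_k."""
    out = 0
    for (k,), c in Poly(expand(expr), m).terms():
        out += c * {0: 1, 1: e1, 2: e2, 3: e3}[k]
    return expand(out)


def moment_rhs(i, j):
    """d<y^i n^j>/dt from the master equation of the four channels."""
    f = y**i * n**j
    total = 0
    # bursty production: rate r*y, n -> n + m
    total += average(r * y * burst_average(f.subs(n, n + m) - f))
    # binding: rate sb*y*n, (y, n) -> (y-1, n-1)
    total += average(sb * y * n * (f.subs({y: y - 1, n: n - 1}) - f))
    # unbinding: rate su*(1-y), y -> y+1
    total += average(su * (1 - y) * (f.subs(y, y + 1) - f))
    # decay: rate d*n, n -> n-1
    total += average(d * n * (f.subs(n, n - 1) - f))
    return sp.collect(sp.expand(total), [r, sb, su, d])


def central(i, j):
    my, mn = NAMES[(1, 0)], NAMES[(0, 1)]
    out = 0
    for (a, b), c in Poly(expand((y - my) ** i * (n - mn) ** j), y, n).terms():
        out += c * NAMES[(a, b)]
    return expand(out)


def zero_kappa4_closure(i, j):
    """Raw <y^i n^j> (order 4) implied by vanishing fourth joint cumulants."""
    cov = {
        (2, 0): central(2, 0), (1, 1): central(1, 1), (0, 2): central(0, 2)
    }
    idx = [0] * i + [1] * j
    a, b, c_, dd = idx

    def cv(p, q):
        key = [0, 0]
        key[p] += 1
        key[q] += 1
        return cov[tuple(key)]

    pairing = cv(a, b) * cv(c_, dd) + cv(a, c_) * cv(b, dd) + cv(a, dd) * cv(b, c_)
    my, mn = NAMES[(1, 0)], NAMES[(0, 1)]
    lower = 0
    for (p, q), c in Poly(expand((y - my) ** i * (n - mn) ** j), y, n).terms():
        if (p, q) != (i, j):
            lower += c * NAMES[(p, q)]
    return sp.simplify(pairing - lower)


if __name__ == "__main__":
    print("# zero-fourth-cumulant closures (3MA)")
    for t in [(3, 1), (2, 2), (1, 3)]:
        print(f"Q{t[0]}{t[1]} =", zero_kappa4_closure(*t))
    print("\n# exact moment equations (closures substituted at run time)")
    for t in TRACKED:
        print(f"d M{t[0]}{t[1]} / dt =", moment_rhs(*t))
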