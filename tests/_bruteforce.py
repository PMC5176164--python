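"""Independent brute-force recomputation of every epoch statistic.

Everything here is written with explicit Python loops from first
principles and shares no code with the package, so it can serve as the
oracle for the featurizer.
"""

import math


def running_mean(x, halfwidth):
    n = len(x)
    out = []
    for i in range(n):
        h = min(halfwidth, i, n - 1 - i)
        window = x[i - h:i + h + 1]
        out.append(sum(window) / len(window))
    return out


def decompose_bruteforce(xyz, rate, static_window_s=3.0):
    """Static/dynamic split plus DBA and posture series, loop by loop."""
    n = len(xyz)
    halfwidth = int(round(static_window_s * rate)) // 2
    static = [[0.0] * 3 for _ in range(n)]
    for k in range(3):
        col = [row[k] for row in xyz]
        sm = running_mean(col, halfwidth)
        for i in range(n):
            static[i][k] = sm[i]
    dynamic = [[xyz[i][k] - static[i][k] for k in range(3)] for i in range(n)]
    pdba = [[abs(v) for v in row] for row in dynamic]
    odba = [sum(row) for row in pdba]
    vedba = [math.sqrt(sum(v * v for v in row)) for row in dynamic]
    q = [math.sqrt(sum(v * v for v in row)) for row in xyz]
    incl, azim = [], []
    for i in range(n):
        mag = math.sqrt(sum(v * v for v in static[i]))
        if mag == 0:
            incl.append(float("nan"))
            azim.append(float("nan"))
        else:
            c = max(-1.0, min(1.0, static[i][2] / mag))
            incl.append(math.acos(c))
            a = math.atan2(static[i][1], static[i][0])
            azim.append(math.pi if a == -math.pi else a)
    return {"static": static, "dynamic": dynamic, "pdba": pdba,
            "odba": odba, "vedba": vedba, "q": q, "incl": incl, "azim": azim}


def _mean(v):
    return sum(v) / len(v)


def _median(v):
    s = sorted(v)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def _sd(v):
    m = _mean(v)
    return math.sqrt(sum((x - m) ** 2 for x in v) / (len(v) - 1))


def _moment(v, p):
    m = _mean(v)
    return sum((x - m) ** p for x in v) / len(v)


def _skew(v):
    m2 = _moment(v, 2)
    return _moment(v, 3) / m2 ** 1.5 if m2 > 0 else 0.0


def _kurtosis(v):
    m2 = _moment(v, 2)
    return _moment(v, 4) / m2 ** 2 - 3.0 if m2 > 0 else 0.0


def _invcv(v):
    sd = _sd(v)
    return _mean(v) / sd if sd > 0 else 0.0


def _ar1(v):
    a, b = v[:-1], v[1:]
    am, bm = _mean(a), _mean(b)
    var = sum((x - am) ** 2 for x in a) / len(a)
    if var == 0:
        return 0.0
    cov = sum((x - am) * (y - bm) for x, y in zip(a, b)) / len(a)
    return cov / var


def _corr(u, v):
    um, vm = _mean(u), _mean(v)
    su = math.sqrt(sum((x - um) ** 2 for x in u) / len(u))
    sv = math.sqrt(sum((x - vm) ** 2 for x in v) / len(v))
    if su == 0 or sv == 0:
        return 0.0
    cov = sum((x - um) * (y - vm) for x, y in zip(u, v)) / len(u)
    return max(-1.0, min(1.0, cov / (su * sv)))


def _nanmean(v):
    vals = [x for x in v if not math.isnan(x)]
    return sum(vals) / len(vals) if vals else float("nan")


def _circular_mean(v):
    s = _nanmean([math.sin(x) for x in v])
    c = _nanmean([math.cos(x) for x in v])
    return math.atan2(s, c)


def _trapz(v, dt):
    return sum((v[i] + v[i + 1]) / 2.0 * dt for i in range(len(v) - 1))


def epoch_features_bruteforce(xyz, rate, epoch_len=13, stride=13,
                              static_window_s=3.0):
    """One dict of the 52 statistics per epoch, all loops."""
    dec = decompose_bruteforce(xyz, rate, static_window_s)
    n = len(xyz)
    dt = 1.0 / rate
    n_epochs = (n - epoch_len) // stride + 1
    rows = []
    for e in range(n_epochs):
        lo = e * stride
        hi = lo + epoch_len
        row = {}
        for k, ax in enumerate("xyz"):
            v = [xyz[i][k] for i in range(lo, hi)]
            row[f"{ax}_mean"] = _mean(v)
            row[f"{ax}_median"] = _median(v)
            row[f"{ax}_sd"] = _sd(v)
            row[f"{ax}_skew"] = _skew(v)
            row[f"{ax}_kurtosis"] = _kurtosis(v)
            row[f"{ax}_min"] = min(v)
            row[f"{ax}_max"] = max(v)
            row[f"{ax}_absmean"] = _mean([abs(x) for x in v])
            row[f"{ax}_invcv"] = _invcv(v)
            row[f"{ax}_ar1"] = _ar1(v)
        qv = dec["q"][lo:hi]
        row["q_mean"] = _mean(qv)
        row["q_sd"] = _sd(qv)
        row["q_min"] = min(qv)
        row["q_max"] = max(qv)
        xv = [xyz[i][0] for i in range(lo, hi)]
        yv = [xyz[i][1] for i in range(lo, hi)]
        zv = [xyz[i][2] for i in range(lo, hi)]
        row["corr_xy"] = _corr(xv, yv)
        row["corr_yz"] = _corr(yv, zv)
        row["corr_xz"] = _corr(xv, zv)
        row["incl_mean"] = _nanmean(dec["incl"][lo:hi])
        row["azim_mean"] = _circular_mean(dec["azim"][lo:hi])
        for k, ax in enumerate("xyz"):
            row[f"pdba_{ax}_mean"] = _mean([dec["pdba"][i][k] for i in range(lo, hi)])
        for name in ("odba", "vedba"):
            v = dec[name][lo:hi]
            row[f"{name}_mean"] = _mean(v)
            row[f"{name}_sd"] = _sd(v)
            row[f"{name}_min"] = min(v)
            row[f"{name}_max"] = max(v)
            row[f"{name}_auc"] = _trapz(v, dt)
        rows.append(row)
    return rows
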