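"""The binary-classification metric suite on a worked example.

Scores a small prediction vector by hand-checkable formulas: confusion
counts, accuracy and its complement error rate, precision/recall/F1,
and the error measures MAE and RMSE (for binary labels MAE equals the
error rate, so 1 - MAE equals accuracy).
"""

from goafs import report

actual    = [1, 0, 1, 1, 0, 1, 0, 1]
predicted = [1, 1, 1, 0, 0, 1, 0, 0]

r = report(actual, predicted)
c = r.confusion
print(f"confusion: TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn}  (n={r.n})")
print(f"accuracy:   {r.accuracy:.4f}   error rate: {r.error_rate:.4f}")
print(f"precision:  {r.precision:.4f}   recall:     {r.recall:.4f}   "
      f"F1: {r.f1:.4f}")
print(f"MAE:        {r.mae:.4f}   RMSE:       {r.rmse:.4f}")
print(f"1 - MAE:    {r.accuracy_from_error:.4f}  (equals accuracy for "
      "binary labels)")
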