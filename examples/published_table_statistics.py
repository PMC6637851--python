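"""Model statistics from the packaged published activity table.

The package ships the printed 80-compound table of experimental and
model-predicted pKi values with its 64/16 train/test split.  From those
per-compound numbers alone, the training fit and the external validation
statistics of the selected two-field model are recomputed.
"""

from fieldsar import ki_to_pki, load_table1, report_table1_stats

table = load_table1()
stats = report_table1_stats(table)
print(f"compounds: {len(table)} "
      f"(train {(table.split == 'train').sum()}, test {(table.split == 'test').sum()})")
print(f"R2 (training fit)        = {stats['r2_train']:.2f}")
print(f"Rtest2 (external)        = {stats['rtest2']:.2f}")
print(f"S_test (external RMSEP)  = {stats['s_test']:.2f}")
print(f"pKi of the most potent compound (Ki = 0.00069 uM) = {ki_to_pki(0.00069):.2f}")
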