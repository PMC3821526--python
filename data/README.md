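# data/

Optional input data.

Place `2ZW3.pdb` here (the Cx26 hemichannel crystal structure, downloadable
from https://www.rcsb.org/structure/2ZW3) to enable:

- the reference-value acceptance tests in `tests/test_acceptance.py`
  (criterion 3), and
- targets t2–t5 in `scripts/acceptance.py`.

The file is not bundled because this repository was produced in an offline
environment; everything else in the package runs on synthetic structures
generated at test time.
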