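# data/

Place the original study's supplementary dataset here as
`dataset_s1.mat` (a MAT container: one struct with one substruct per
participant, each holding a 26×60 reaction-time cell array and a 23×3
temporal-order-judgment array) to enable the reproduction test in
`tests/test_acceptance.py` and analyses via
`twindow run --input data/dataset_s1.mat`.

The file is a supplementary download and is not redistributed with the
package; every other test and script generates its inputs synthetically.
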