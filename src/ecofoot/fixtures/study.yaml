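# Metadata for the packaged study fixtures (eight-city lower-Yangtze
# urban agglomeration, accounting years 2013-2017; item-level accounts
# are available for 2017 only).
#
# The resident population is calibrated from the published (total,
# per-capita) column pairs of the 2017 accounts: it is the value for
# which every reproducible printed per-capita cell rounds correctly at
# its printed precision.  The tea yield below is likewise calibrated to
# the published footprint total of that item (the printed yield is
# inconsistent with the row's own production and downstream cells).
population: 43344500
year: 2017
first_year: 2013
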