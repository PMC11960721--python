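# Published relative cover fractions at the HBEF site:
# observed releve, uncalibrated (blind) model run, calibrated model run.
# Values are rounded to two decimals; absent species have no row.
species,observed,blind,calibrated
Acer pensylvanicum,0.01,0.04,0.05
Acer saccharum,0.01,0.00,0.02
Betula alleghaniensis,0.02,0.00,0.03
Clintonia borealis,0.04,0.04,0.04
Dennstaedtia punctilobula,0.00,0.68,0.03
Dryopteris intermedia,0.32,0.00,0.33
Fagus grandifolia,0.07,0.00,0.05
Huperzia lucidula,0.10,0.00,0.06
Maianthemum canadense,0.03,0.00,0.00
Maianthemum racemosum,0.01,0.00,0.00
Medeola virginiana,0.00,0.00,0.00
Monotropa uniflora,0.00,0.00,0.00
Oclemena acuminata,0.01,0.00,0.00
Oxalis montana,0.02,0.00,0.01
Trientalis borealis,0.00,0.00,0.00
Trillium spp,0.00,0.00,0.00
Uvularia sessilifolia,0.04,0.00,0.05
Viburnum acerifolium,0.29,0.25,0.34
Viola rotundifolia,0.00,0.00,0.00
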