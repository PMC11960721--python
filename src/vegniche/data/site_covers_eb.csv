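# Published relative cover fractions at the EB site:
# observed releve, uncalibrated (blind) model run, calibrated model run.
# Values are rounded to two decimals; absent species have no row.
species,observed,blind,calibrated
Abies balsamea,0.00,0.14,0.01
Acer pensylvanicum,0.07,0.01,0.02
Acer rubrum,0.02,0.14,0.02
Acer saccharum,0.03,0.00,0.01
Aralia nudicaulis,0.03,0.00,0.04
Arisaema triphyllum,0.00,0.00,0.00
Betula alleghaniensis,0.13,0.14,0.12
Coptis trifolia,0.01,0.00,0.00
Cornus alternifolia,0.00,0.00,0.00
Cornus canadensis,0.01,0.03,0.02
Dennstaedtia punctilobula,0.00,0.02,0.02
Diervilla lonicera,0.00,0.00,0.00
Dryopteris campyloptera,0.21,0.00,0.15
Fagus grandifolia,0.25,0.01,0.22
Fragaria virginiana,0.00,0.01,0.01
Fraxinus americana,0.00,0.01,0.01
Gymnocarpium dryopteris,0.00,0.00,0.00
Lonicera canadensis,0.00,0.00,0.00
Maianthemum canadense,0.02,0.00,0.00
Medeola virginiana,0.00,0.00,0.00
Osmunda claytoniana,0.05,0.00,0.03
Phegopteris connectilis,0.00,0.00,0.00
Picea rubens,0.07,0.10,0.08
Polygonum convolvulus,0.00,0.00,0.00
Prunus serotina,0.00,0.00,0.00
Ribes glandulosum,0.00,0.00,0.01
Sorbus americana,0.00,0.10,0.01
Thelypteris noveboracensis,0.00,0.05,0.00
Trientalis borealis,0.02,0.00,0.00
Tsuga canadensis,0.02,0.14,0.01
Uvularia sessilifolia,0.05,0.00,0.01
Viburnum acerifolium,0.00,0.00,0.00
Viburnum lantanoides,0.00,0.12,0.02
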