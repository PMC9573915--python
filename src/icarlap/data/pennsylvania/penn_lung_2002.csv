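county,y,E
adams,55,69.6273047893242
allegheny,1275,1182.42803561693
armstrong,49,67.6101226360002
beaver,172,172.558055235991
bedford,37,44.1901324574679
berks,308,300.70597943937
blair,127,115.069654764999
bradford,59,53.2376442441653
bucks,454,428.797480887922
butler,158,134.79770459263
cambria,121,149.846027468058
cameron,8,5.94590483926775
carbon,42,55.4752105095854
centre,61,79.4040126174385
chester,291,300.124058404598
clarion,32,33.9066468574541
clearfield,73,73.8532396957984
clinton,27,33.0120293041182
columbia,58,53.3121107846569
crawford,74,75.0250240735215
cumberland,132,170.866603286877
dauphin,168,199.809037894605
delaware,485,454.545970547404
elk,31,31.5437362186283
erie,231,216.203436393064
fayette,150,137.810483770792
forest,4,5.40358256752572
franklin,105,109.888662310611
fulton,11,11.5948022343766
greene,38,33.093111799225
huntingdon,26,36.6595152521149
indiana,70,71.0901297259622
jefferson,34,42.5558003769292
juniata,6,18.7351457126709
lackawanna,181,204.172754048185
lancaster,301,357.237966095397
lawrence,76,91.3030561462005
lebanon,77,103.076598212853
lehigh,252,259.874790091335
luzerne,285,309.688036233919
lycoming,98,101.231639348028
mckean,35,40.1052268426258
mercer,98,111.790652951053
mifflin,45,40.7746299533373
monroe,110,100.094713806281
montgomery,599,608.691818716506
montour,8,16.0813304762948
northampton,236,222.731099237606
northumberland,83,90.872134416746
perry,31,31.0372543908077
philadelphia,1415,1219.10269624166
pike,35,39.8652690480346
potter,22,16.0032095198016
schuylkill,136,147.93771161082
snyder,28,28.8789023967197
somerset,54,74.5234969940355
sullivan,3,7.41968166627405
susquehanna,34,36.174265855514
tioga,28,35.7563815147819
union,28,30.8338361442133
venango,70,51.1410138024989
warren,35,39.2307102669936
washington,194,189.097719949832
wayne,45,44.4901610536094
westmoreland,372,351.175955435742
wyoming,14,21.0092239053421
york,279,288.86966631687
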