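# Synthetic stand-in gene list: 61 up-regulated and 54 down-regulated
# AGI-style identifiers generated at random; not real differential-expression calls.
gene_id	label
AT3G20770	up
AT4G07320	up
AT1G71230	up
AT1G48930	up
AT5G08600	up
AT5G29140	up
AT1G12260	up
AT4G55810	up
AT1G32540	up
AT1G73220	up
AT4G08740	up
AT5G17220	up
AT2G77410	up
AT1G76640	up
AT5G52990	up
AT1G29970	up
AT1G73960	up
AT2G38950	up
AT4G19900	up
AT5G16430	up
AT5G41430	up
AT5G24680	up
AT1G77230	up
AT5G25620	up
AT3G13770	up
AT5G09220	up
AT5G08810	up
AT5G27990	up
AT4G70690	up
AT4G42170	up
AT4G77750	up
AT4G48390	up
AT3G33560	up
AT2G32990	up
AT1G76290	up
AT3G69830	up
AT4G46020	up
AT4G38740	up
AT5G10590	up
AT1G68100	up
AT4G22620	up
AT3G20920	up
AT4G56270	up
AT1G11170	up
AT5G76100	up
AT3G45580	up
AT3G78900	up
AT4G77000	up
AT4G10010	up
AT1G36380	up
AT4G09510	up
AT1G41580	up
AT5G59410	up
AT3G51560	up
AT3G03950	up
AT4G47590	up
AT2G16340	up
AT4G08720	up
AT2G38670	up
AT2G33450	up
AT4G52240	up
AT4G11560	down
AT2G59870	down
AT4G73010	down
AT3G18940	down
AT4G73110	down
AT3G55430	down
AT3G50860	down
AT2G20780	down
AT1G24090	down
AT2G31400	down
AT2G02580	down
AT4G78210	down
AT2G35430	down
AT3G01530	down
AT2G55910	down
AT5G49390	down
AT5G75230	down
AT3G17440	down
AT5G08070	down
AT4G74300	down
AT4G53170	down
AT4G52650	down
AT1G64110	down
AT4G09150	down
AT2G09820	down
AT2G58750	down
AT2G15400	down
AT3G79730	down
AT1G14410	down
AT1G75280	down
AT2G71330	down
AT1G48650	down
AT5G04340	down
AT1G28250	down
AT5G50310	down
AT2G34060	down
AT3G79940	down
AT3G63140	down
AT1G16110	down
AT4G62070	down
AT4G64410	down
AT3G12250	down
AT2G14390	down
AT3G35700	down
AT4G22160	down
AT5G04020	down
AT2G70230	down
AT3G20210	down
AT5G04540	down
AT5G40070	down
AT1G35220	down
AT5G49060	down
AT2G47620	down
AT2G70800	down
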