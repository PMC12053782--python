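study_id,year,method,question,repeated,setting,sleep_type,days,has_with_recall,has_without_recall,has_no_report
Parker2000,2000,Other,Other,,,,,yes,no,no
Takeuchi2001,2001,Alarm,Mind,Repeated,Lab,Night,>1,yes,yes,yes
Stickgold2001,2001,Other,Mind,Repeated,Home,Night,>1,yes,no,no
Takeuchi2003,2003,Alarm,Other,Repeated,Lab,Night,>1,yes,yes,yes
Palagnini2004,2004,Name,Mind,Single,Lab,Nap,>1,yes,no,no
Fosse2004,2004,Other,Mind,Repeated,Home,Night,>1,yes,no,no
Wittmann2004,2004,Name,Mind,Repeated,Lab,Night,>1,yes,yes,yes
StOnge2005,2005,Other,Mind,Repeated,Lab,Night,1,yes,no,no
Strauch2005,2005,Name,Dream,Repeated,Lab,Night,>1,yes,no,no
Grenier2005,2005,Name,Mind,Repeated,Lab,Night,1,yes,no,no
Wamsley2007,2007,Name,Mind,Repeated,Lab,Night,1,yes,yes,yes
Weigand2007,2007,Alarm,Mind,Both,Lab,Night,1,yes,no,no
Daoust2008,2008,Other,Mind,Repeated,Lab,Night,1,yes,yes,yes
Wamsley2008,2008,Name,Mind,Repeated,Lab,Nap,>1,yes,no,no
Noreika2009,2009,Alarm,Mind,Repeated,Lab,Night,>1,yes,yes,yes
Lusignan2009,2009,Other,Mind,Repeated,Lab,Night,>1,yes,yes,yes
LaraCarrasco2009,2009,Alarm,Mind,Repeated,Lab,Night,1,yes,no,no
Lusignan2010,2010,Other,Mind,Repeated,Lab,Night,1,yes,yes,yes
Wamsley2010a,2010,Other,Mind,Repeated,Lab,Nap,1,yes,no,no
Wamsley2010b,2010,Other,Mind,Repeated,Home,Night,>1,yes,no,no
Schredl2010,2010,Name,Mind,Repeated,Lab,Night,1,yes,no,no
Chellappa2011,2011,Other,Dream,Single,Lab,Nap,>1,yes,no,no
Kahan2011,2011,Alarm,Other,Repeated,Home,Night,1,yes,no,no
Blagrove2011,2011,Alarm,Mind,Repeated,Lab,Night,>1,yes,no,no
Marzano2011,2011,Name,Dream,Repeated,Lab,Night,1,yes,no,no
Oudiette2012,2012,Name,Mind,Repeated,Lab,Night,>1,yes,no,no
Kusse2012,2012,,Mind,Repeated,Lab,Nap,>1,yes,no,no
Chellappa2012,2012,Other,Dream,Single,Lab,Nap,>1,yes,no,no
Stenstrom2012,2012,Name,Other,Repeated,Lab,Night,>1,yes,yes,yes
Siclari2013,2013,Alarm,Mind,Repeated,Lab,Night,>1,yes,yes,yes
Schredl2014,2014,Other,Mind,Repeated,Lab,Night,1,yes,no,no
Sikka2014,2014,Alarm,Dream,Repeated,Lab,Night,>1,yes,no,no
Yu2014,2014,,Mind,Repeated,Lab,Night,1,yes,no,no
Eichenlaub2014,2014,Other,Mind,Single,Lab,Night,1,yes,yes,yes
Carr2015,2015,Alarm,Dream,Single,Lab,Nap,1,yes,no,no
VanRijn2015,2015,Alarm,Mind,Repeated,Both,Night,>1,yes,no,no
Yu2016,2016,,Mind,Repeated,Lab,Night,1,yes,yes,yes
Nefjodov2016,2016,Other,Mind,Repeated,Lab,Night,1,yes,no,no
Scarpelli2017,2017,Name,Mind,Repeated,Lab,Nap,1,yes,yes,yes
Siclari2017,2017,Alarm,Mind,Repeated,Lab,Night,>1,yes,yes,yes
Sikka2017,2017,Alarm,Dream,Repeated,Lab,Night,>1,yes,no,no
Solomonova2018,2018,Alarm,,Repeated,Lab,Nap,1,yes,no,no
Eichenlaub2018,2018,Alarm,Mind,Repeated,Lab,Night,1,yes,no,no
Feige2018,2018,Alarm,Mind,Repeated,Lab,Night,>1,yes,no,no
Siclari2018,2018,Alarm,Mind,Repeated,Lab,Night,>1,yes,yes,yes
Blagrove2019,2019,Alarm,Mind,Repeated,Lab,Night,1,yes,no,no
Wamsley2019,2019,Name,Mind,Repeated,Lab,Night,1,yes,no,no
Schoch2019,2019,Other,Mind,Repeated,Lab,Night,1,yes,no,no
Zhang2019,2019,Name,Mind,Repeated,Lab,Night,1,yes,no,no
Klepel2019,2019,Other,Mind,Single,Lab,Night,1,yes,no,no
Sikka2019,2019,Alarm,Dream,Repeated,Lab,Night,>1,yes,no,no
Sterpenich2020,2020,Alarm,Mind,Repeated,Lab,Night,1,yes,yes,yes
BlanchetteCarriere2020,2020,,Dream,Single,Lab,Nap,>1,yes,no,no
PicardDeland2020,2020,Alarm,Mind,Single,Lab,Night,1,yes,no,no
Yu2020,2020,,Mind,Repeated,Lab,Night,>1,yes,no,no
Vallat2020,2020,Name,Dream,Single,Lab,Nap,1,yes,no,no
Martin2020,2020,Name,Mind,Repeated,Lab,Night,>1,yes,yes,yes
Scarpelli2020,2020,Name,Mind,Single,Lab,Night,1,yes,no,no
Spano2020,2020,Alarm,Mind,Repeated,Home,Night,1,yes,no,no
Stephan2021,2021,Alarm,Mind,Repeated,Lab,Night,>1,yes,yes,yes
PicardDeland2021a,2021,Alarm,Dream,Single,Lab,Nap,1,yes,no,no
Pires2021,2021,,Dream,Repeated,Lab,Night,>1,yes,no,no
PicardDeland2021b,2021,Alarm,Mind,Repeated,Lab,,,yes,yes,yes
Aamodt2021,2021,Alarm,Mind,Repeated,Lab,Nap,1,yes,yes,yes
Wamsley2022,2022,Name,Mind,Repeated,Lab,Night,1,yes,no,no
PicardDeland2023,2023,Name,Mind,Repeated,Lab,Night,1,yes,no,no
Juan2023,2023,Alarm,Mind,Repeated,Lab,Night,1,yes,yes,yes
Sebastiani2023,2023,Other,Dream,Single,Lab,Nap,1,yes,no,no
Aamodt2023,2023,Alarm,Mind,Repeated,Lab,Night,1,yes,yes,yes
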